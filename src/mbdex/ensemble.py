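"""RMSD precision statistics over a multi-model NMR coordinate ensemble.

An NMR structure is deposited as an ensemble of models that all satisfy
the experimental restraints; the spread of the ensemble (RMSD of each
model to the mean coordinates, or averaged over all model pairs) is the
standard precision statistic.  Superposition is the Kabsch least-squares
rigid-body fit restricted to proper rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, FitFailureError, InvalidInputError

__all__ = [
    "ATOM_CLASSES",
    "CoordinateEnsemble",
    "AtomSelection",
    "superpose",
    "rmsd_to_mean",
    "pairwise_rmsd",
    "RmsdReport",
]

#: named atom sets; None means "all non-hydrogen atoms"
ATOM_CLASSES: dict[str, frozenset[str] | None] = {
    "backbone": frozenset({"N", "CA", "C"}),
    "heavy": None,
    "nucleic-backbone": frozenset({"P", "O5'", "C5'", "C4'", "C3'", "O3'"}),
    "all": None,
}


@dataclass
class CoordinateEnsemble:
    """Multi-model coordinates sharing one (chain, residue, atom) roster.

    ``roster`` is a list of (chain id, residue number, atom name, element)
    tuples; ``coords`` has shape (n_models, n_atoms, 3) in Angstrom.
    """

    roster: list[tuple[str, int, str, str]]
    coords: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError("coords must be (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.roster):
            raise InvalidInputError("coords second axis must match roster length")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, sel: "AtomSelection") -> np.ndarray:
        """Boolean mask over the roster for a selection."""
        mask = np.array([sel.matches(*entry) for entry in self.roster])
        if mask.sum() < 3:
            raise InvalidInputError(
                f"selection resolves to {int(mask.sum())} atoms; need >= 3"
            )
        return mask


@dataclass
class AtomSelection:
    """Union of per-chain residue-range selections with an atom class.

    ``specs`` is a list of (chain id, (lo, hi) or None, atom class name);
    a None range keeps every residue of the chain.  Atom classes follow
    the dominant conventions: protein backbone = N, CA, C; nucleic
    backbone = P, O5', C5', C4', C3', O3'; heavy = all non-hydrogen.
    """

    specs: list[tuple[str, tuple[int, int] | None, str]] = field(default_factory=list)

    @classmethod
    def parse(cls, *exprs: str) -> "AtomSelection":
        """Parse 'chain:start-end[:class]' expressions, e.g. 'A:86-140:backbone'."""
        specs = []
        for expr in exprs:
            parts = expr.split(":")
            if len(parts) not in (2, 3):
                raise InvalidInputError(f"bad selection {expr!r}")
            chain = parts[0]
            rng: tuple[int, int] | None
            if parts[1] in ("", "*"):
                rng = None
            else:
                lo, _, hi = parts[1].partition("-")
                rng = (int(lo), int(hi or lo))
            klass = parts[2] if len(parts) == 3 else "heavy"
            if klass not in ATOM_CLASSES:
                raise InvalidInputError(f"unknown atom class {klass!r}")
            specs.append((chain, rng, klass))
        return cls(specs)

    def matches(self, chain: str, resnum: int, atom: str, element: str) -> bool:
        for spec_chain, rng, klass in self.specs:
            if spec_chain not in ("*", chain):
                continue
            if rng is not None and not (rng[0] <= resnum <= rng[1]):
                continue
            allowed = ATOM_CLASSES[klass]
            if allowed is None:
                if element.upper() != "H":
                    return True
            elif atom in allowed:
                return True
        return False

    def describe(self) -> str:
        return " + ".join(
            f"{c}:{'*' if r is None else f'{r[0]}-{r[1]}'}:{k}" for c, r, k in self.specs
        )


@dataclass
class RmsdReport:
    """Ensemble precision statistic."""

    mean_rmsd: float
    sd_rmsd: float
    mode: str              # 'to-mean' or 'pairwise'
    n_models: int
    selection: str = ""
    n_atoms: int = 0


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation least-squares superposition (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation has determinant +1 (reflections rejected) and the returned
    rmsd is the global minimum over rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InvalidInputError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise InvalidInputError("need >= 3 atoms to superpose")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    X, Y = mobile - cm, reference - cr
    if np.linalg.matrix_rank(X) < 2:
        raise DegenerateGeometryError("collinear mobile coordinates")
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    diff = (X @ R.T) - Y
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def _selected_coords(ens: CoordinateEnsemble, sel: AtomSelection | None) -> np.ndarray:
    if ens.n_models < 2:
        raise InvalidInputError("need >= 2 models for an RMSD statistic")
    if sel is None:
        return ens.coords
    return ens.coords[:, ens.select(sel), :]


def rmsd_to_mean(
    ens: CoordinateEnsemble,
    sel: AtomSelection | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> RmsdReport:
    """Per-model RMSD to the iteratively converged mean coordinates.

    Models are superposed onto the evolving mean and the mean recomputed
    until it shifts by less than ``tol`` Angstrom (RMS over atoms).
    Reports mean +/- sd of the per-model RMSD to the converged mean.
    """
    coords = _selected_coords(ens, sel)
    fitted = np.empty_like(coords)
    mean = coords[0].copy()
    for _ in range(max_iter):
        for m in range(coords.shape[0]):
            R, t, _ = superpose(coords[m], mean)
            fitted[m] = coords[m] @ R.T + t
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    else:
        raise FitFailureError(f"mean coordinates did not converge in {max_iter} iterations")
    rmsds = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=1))
    return RmsdReport(
        mean_rmsd=float(rmsds.mean()),
        sd_rmsd=float(rmsds.std(ddof=1)) if rmsds.size > 1 else 0.0,
        mode="to-mean",
        n_models=ens.n_models,
        selection=sel.describe() if sel else "all atoms",
        n_atoms=coords.shape[1],
    )


def pairwise_rmsd(
    ens: CoordinateEnsemble, sel: AtomSelection | None = None
) -> RmsdReport:
    """Mean +/- sd RMSD over all unordered model pairs, each pair
    superposed independently."""
    coords = _selected_coords(ens, sel)
    n = coords.shape[0]
    vals = [
        superpose(coords[j], coords[i])[2] for i in range(n) for j in range(i + 1, n)
    ]
    vals = np.array(vals)
    return RmsdReport(
        mean_rmsd=float(vals.mean()),
        sd_rmsd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        mode="pairwise",
        n_models=n,
        selection=sel.describe() if sel else "all atoms",
        n_atoms=coords.shape[1],
    )
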