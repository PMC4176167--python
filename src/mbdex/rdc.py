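"""Residual dipolar coupling analysis: SVD alignment-tensor fit and Q-factor.

An RDC measured for a bond vector v depends on the molecular alignment
tensor S (symmetric, traceless) as D = v^T S v.  Expanding in the five
independent components gives a linear system, one row

    [y^2 - x^2,  z^2 - x^2,  2xy,  2xz,  2yz]

per bond vector, solved by singular value decomposition.  The tensor is
fit directly in Hz (the dipolar interaction constant and order-parameter
scaling are absorbed), since the quality factor

    Q = rms(D_obs - D_calc) / rms(D_obs)

is invariant to that overall scale.  A low Q means the structure's bond
orientations are consistent with the couplings; refitting after excluding
a residue block tests whether that block's conformation in the model is
what spoils the agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InvalidInputError, UnderDeterminedError

__all__ = [
    "BondVectorSet",
    "RdcSet",
    "AlignmentTensor",
    "QReport",
    "svd_fit",
    "back_calculate",
    "q_factor",
]

_COND_LIMIT = 1e8


@dataclass
class BondVectorSet:
    """Unit bond vectors (e.g. amide N-H) in the molecular frame."""

    residues: np.ndarray  # residue ids, unique
    vectors: np.ndarray   # (n, 3), unit norm

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise InvalidInputError("vectors must be (n, 3)")
        if self.residues.size != self.vectors.shape[0]:
            raise InvalidInputError("residues and vectors must match")
        if np.unique(self.residues).size != self.residues.size:
            raise InvalidInputError("residue ids must be unique")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidInputError("bond vectors must have unit norm (1e-6)")


@dataclass
class RdcSet:
    """Observed (or back-calculated) couplings per residue, in Hz."""

    residues: np.ndarray
    d: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.d = np.asarray(self.d, dtype=float)
        if self.residues.size != self.d.size:
            raise InvalidInputError("residues and couplings must match")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.size != self.d.size:
                raise InvalidInputError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise InvalidInputError("uncertainties must be > 0 where present")


@dataclass
class AlignmentTensor:
    """Saupe alignment tensor in the 5-component representation.

    ``saupe`` holds (Syy, Szz, Sxy, Sxz, Syz) with Sxx = -Syy - Szz.
    Principal-frame quantities use the convention |Szz| >= |Syy| >= |Sxx|,
    axial magnitude Da = Szz/2 and rhombicity R = (2/3)(Sxx - Syy)/Szz,
    which lies in [0, 2/3].
    """

    saupe: np.ndarray

    def __post_init__(self) -> None:
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (5,):
            raise InvalidInputError("saupe must have 5 components")

    @property
    def matrix(self) -> np.ndarray:
        syy, szz, sxy, sxz, syz = self.saupe
        sxx = -syy - szz
        return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])

    def _principal(self) -> tuple[np.ndarray, np.ndarray]:
        vals, vecs = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(vals))  # |Sxx| <= |Syy| <= |Szz|
        vals = vals[order[[0, 1, 2]]]
        vecs = vecs[:, order[[0, 1, 2]]]
        if np.linalg.det(vecs) < 0:
            vecs[:, 0] = -vecs[:, 0]
        return vals, vecs  # (Sxx, Syy, Szz), columns x,y,z

    @property
    def da(self) -> float:
        """Axial magnitude Szz/2 (Hz in the effective-tensor convention)."""
        vals, _ = self._principal()
        return float(vals[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        vals, _ = self._principal()
        sxx, syy, szz = vals
        if szz == 0:
            return 0.0
        return float((2.0 / 3.0) * (sxx - syy) / szz)

    @property
    def principal_axes(self) -> np.ndarray:
        """Rotation to the principal frame (columns = x, y, z axes)."""
        return self._principal()[1]

    @classmethod
    def axial(cls, da: float, axis: str = "z") -> "AlignmentTensor":
        """Axially symmetric tensor with magnitude ``da`` along a lab axis."""
        szz = 2.0 * da
        if axis == "z":
            return cls(np.array([-szz / 2.0, szz, 0.0, 0.0, 0.0]))
        if axis == "x":
            # Sxx = 2da -> Syy = Szz = -da
            return cls(np.array([-da, -da, 0.0, 0.0, 0.0]))
        if axis == "y":
            return cls(np.array([2.0 * da, -da, 0.0, 0.0, 0.0]))
        raise InvalidInputError("axis must be one of x, y, z")


@dataclass
class QReport:
    """Quality of agreement between observed and back-calculated couplings."""

    q: float                 # fraction; multiply by 100 for %
    rms_dev: float           # Hz
    n_used: int
    excluded: list = field(default_factory=list)

    @property
    def q_percent(self) -> float:
        return 100.0 * self.q


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    x, y, z = vectors[:, 0], vectors[:, 1], vectors[:, 2]
    return np.column_stack(
        [y**2 - x**2, z**2 - x**2, 2 * x * y, 2 * x * z, 2 * y * z]
    )


def _match(vectors: BondVectorSet, rdcs: RdcSet, exclude=None):
    excl_ranges = [tuple(r) for r in (exclude or [])]

    def excluded(res: int) -> bool:
        return any(lo <= res <= hi for lo, hi in excl_ranges)

    vmap = {int(r): v for r, v in zip(vectors.residues, vectors.vectors)}
    res, vv, dd = [], [], []
    for r, d in zip(rdcs.residues, rdcs.d):
        r = int(r)
        if r in vmap and not excluded(r):
            res.append(r)
            vv.append(vmap[r])
            dd.append(d)
    return np.array(res, dtype=int), np.array(vv), np.array(dd), excl_ranges


def svd_fit(
    vectors: BondVectorSet, rdcs: RdcSet, exclude=None
) -> tuple[AlignmentTensor, QReport]:
    """Least-norm SVD fit of the alignment tensor to matched couplings.

    Parameters
    ----------
    exclude : iterable of (lo, hi) residue ranges, optional
        Couplings whose residue falls in any range are left out of the fit
        (used e.g. to test whether a suspect structural segment degrades
        the agreement).
    """
    res, vv, dd, excl = _match(vectors, rdcs, exclude)
    if res.size < 5:
        raise UnderDeterminedError(
            f"need >= 5 matched couplings after exclusion, got {res.size}"
        )
    A = _design_matrix(vv)
    s = np.linalg.svd(A, compute_uv=False)
    cond = s[0] / s[-1] if s[-1] > 0 else math.inf
    if cond > _COND_LIMIT:
        raise DegenerateGeometryError(
            f"bond-vector geometry is rank deficient (condition number {cond:.3g})"
        )
    coef, *_ = np.linalg.lstsq(A, dd, rcond=None)
    tensor = AlignmentTensor(coef)
    calc = RdcSet(residues=res, d=A @ coef)
    report = q_factor(RdcSet(residues=res, d=dd), calc)
    report.excluded = excl
    return tensor, report


def back_calculate(tensor: AlignmentTensor, vectors: BondVectorSet) -> RdcSet:
    """Couplings D = v^T S v for every bond vector.

    For an axially symmetric tensor this is Da*(3cos^2(theta) - 1) with
    theta measured from the principal axis.
    """
    A = _design_matrix(vectors.vectors)
    return RdcSet(residues=vectors.residues.copy(), d=A @ tensor.saupe)


def q_factor(obs: RdcSet, calc: RdcSet, normalize: str = "rms_obs") -> QReport:
    """Quality factor between matched observed and calculated couplings.

    ``normalize='rms_obs'`` (default) divides the rms deviation by the rms
    observed coupling; ``normalize='tensor'`` divides by the rms coupling
    expected from the spread of the observed values under a random
    orientation distribution, sqrt(2*Da^2*(4 + 3R^2)/5) — only available
    when a tensor magnitude can be inferred, so here it uses the calc set's
    own spread as a proxy and is offered for comparison, not as default.
    """
    if obs.residues.size == 0 or obs.residues.size != calc.residues.size:
        raise InvalidInputError("observed and calculated sets must match, non-empty")
    if not np.array_equal(obs.residues, calc.residues):
        raise InvalidInputError("residue ids of obs and calc differ")
    rms_obs = math.sqrt(float(np.mean(obs.d**2)))
    if rms_obs == 0:
        raise InvalidInputError("all-zero observed couplings: Q undefined")
    rms_dev = math.sqrt(float(np.mean((obs.d - calc.d) ** 2)))
    if normalize == "rms_obs":
        denom = rms_obs
    elif normalize == "tensor":
        denom = math.sqrt(float(np.mean(calc.d**2)))
        if denom == 0:
            raise InvalidInputError("zero calculated couplings: cannot normalize")
    else:
        raise InvalidInputError(f"unknown normalization {normalize!r}")
    return QReport(q=rms_dev / denom, rms_dev=rms_dev, n_used=int(obs.residues.size))
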