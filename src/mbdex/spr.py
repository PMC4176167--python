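"""Steady-state SPR binding analysis: 1:1 Langmuir isotherm fits.

The equilibrium response of a surface-captured DNA ligand to an analyte at
concentration c follows R(c) = Rmax * c / (KD + c).  Fitting response
versus concentration yields the dissociation constant KD and the maximal
response Rmax; KD ratios between DNA variants quantify binding selectivity
(e.g. preference of a methyl-CpG binding domain for methylated over
unmethylated or mismatched CpG sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import FitFailureError, InvalidInputError, UnderDeterminedError

__all__ = [
    "BindingIsotherm",
    "LangmuirFit",
    "steady_state_response",
    "fit_langmuir",
    "selectivity_ratio",
]


@dataclass
class BindingIsotherm:
    """Steady-state responses at a series of analyte concentrations."""

    concentrations: np.ndarray  # uM
    responses: np.ndarray       # response units
    variant: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise InvalidInputError("concentrations and responses must match")
        if np.any(self.concentrations <= 0):
            raise InvalidInputError("concentrations must be > 0")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.responses = self.responses[order]
        if np.any(np.diff(self.concentrations) == 0):
            raise InvalidInputError("duplicate concentrations")


@dataclass
class LangmuirFit:
    """Fitted 1:1 Langmuir parameters."""

    kd: float          # uM
    rmax: float        # response units
    chi2: float        # sum of squared residuals
    kd_stderr: float   # uM
    variant: str = ""


def steady_state_response(kd: float, rmax: float, conc) -> np.ndarray | float:
    """1:1 Langmuir steady-state response rmax*conc/(kd + conc)."""
    conc = np.asarray(conc, dtype=float)
    if kd <= 0 or rmax <= 0 or np.any(conc <= 0):
        raise InvalidInputError("kd, rmax and concentrations must be > 0")
    out = rmax * conc / (kd + conc)
    return float(out) if out.ndim == 0 else out


def fit_langmuir(iso: BindingIsotherm) -> LangmuirFit:
    """Unweighted least-squares fit of (KD, Rmax), both bounded positive.

    Warns when the top concentration is below the fitted KD, where Rmax is
    poorly constrained and the two parameters are strongly correlated.
    """
    c, r = iso.concentrations, iso.responses
    if np.unique(c).size < 4:
        raise UnderDeterminedError("need >= 4 distinct concentrations")
    if c.max() / c.min() < 5:
        raise UnderDeterminedError("concentration series must span >= 5-fold")
    if np.all(r <= 0) or np.ptp(r) == 0:
        raise FitFailureError("responses carry no binding signal")

    p = lmfit.Parameters()
    half = r.max() / 2.0
    kd0 = float(c[np.argmin(np.abs(r - half))])
    p.add("kd", value=max(kd0, c.min() * 0.1), min=1e-9)
    p.add("rmax", value=float(r.max()), min=1e-12)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return r - p["rmax"].value * c / (p["kd"].value + c)

    out = lmfit.minimize(residual, p, method="least_squares")
    if not out.success:
        raise FitFailureError(f"Langmuir fit did not converge: {out.message}")
    kd = out.params["kd"].value
    if c.max() < kd:
        warnings.warn(
            f"max concentration {c.max():g} < fitted KD {kd:g}: "
            "Rmax poorly constrained", stacklevel=2,
        )
    stderr = out.params["kd"].stderr
    return LangmuirFit(
        kd=float(kd),
        rmax=float(out.params["rmax"].value),
        chi2=float(np.sum(residual(out.params) ** 2)),
        kd_stderr=float(stderr) if stderr is not None else float("nan"),
        variant=iso.variant,
    )


def selectivity_ratio(kd_ref: float, kd_other: float) -> float:
    """Fold preference for the reference ligand: kd_other / kd_ref (> 1
    means the reference binds more tightly)."""
    if kd_ref <= 0 or kd_other <= 0:
        raise InvalidInputError("dissociation constants must be > 0")
    return kd_other / kd_ref
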