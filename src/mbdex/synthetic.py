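"""Seeded synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure its consumer assumes —
two-site slow-exchange intensity build-ups with Gaussian noise scaled to
the maximum intensity, 1:1 Langmuir isotherms with fractional response
noise, RDC sets from a known alignment tensor over bond vectors uniform
on the sphere, and coordinate ensembles built by isotropically jittering
a template structure.  All randomness flows through per-stage substreams
of one seed, so the same (seed, parameters) pair always reproduces the
same data and adding a new generator never perturbs an existing fixture.

Default operating points are frozen to the measured study conditions:
site lifetimes of 40/23 ms (MBD4 at 200/333 uM) and 66/34 ms (cMBD2 at
185/370 uM), the ten-delay 11.9-211.8 ms sampling, and the eight
steady-state SPR (KD, Rmax) pairs for the methylated, mismatched,
hydroxymethylated and unmethylated DNA variants.
"""

from __future__ import annotations

import numpy as np

from .ensemble import CoordinateEnsemble
from .errors import InvalidInputError
from .exchange import (
    PAPER_DELAYS_S,
    ExchangeModel,
    IntensitySeries,
    fit_nz_exchange,
    simulate_nz_intensities,
)
from .rdc import AlignmentTensor, BondVectorSet, RdcSet, back_calculate
from .spr import BindingIsotherm, fit_langmuir, steady_state_response

__all__ = [
    "EXCHANGE_OPERATING_POINTS",
    "SPR_OPERATING_POINTS",
    "stage_rng",
    "gen_exchange_series",
    "gen_spr_isotherm",
    "gen_rdc_set",
    "gen_ensemble",
    "synthetic_template",
    "lifetime_recovery_experiment",
    "kd_recovery_experiment",
]

#: measured intermolecular-exchange mean lifetimes (ms) by condition
EXCHANGE_OPERATING_POINTS: dict[str, float] = {
    "mbd4_200uM": 40.0,
    "mbd4_333uM": 23.0,
    "cmbd2_185uM": 66.0,
    "cmbd2_370uM": 34.0,
}

#: steady-state SPR operating points: (variant, KD in uM, Rmax in RU)
SPR_OPERATING_POINTS: list[tuple[str, float, float]] = [
    ("mCpG", 6.4, 0.74),
    ("TpG", 11.5, 0.59),
    ("CpG", 17.2, 0.91),
    ("hmCpG", 14.2, 0.72),
    ("Y109F-mCpG", 7.9, 0.63),
    ("Y109F-TpG", 14.0, 0.51),
    ("Y109F-CpG", 19.6, 0.76),
    ("Y109F-hmCpG", 16.0, 0.59),
]

# fixed substream indices; append-only so streams never shift
_STAGE_KEYS = {"exchange": 0, "spr": 1, "rdc": 2, "ensemble": 3}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for one generator stage of one seed."""
    if stage not in _STAGE_KEYS:
        raise InvalidInputError(f"unknown stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_KEYS[stage]]))


def gen_exchange_series(
    model: ExchangeModel,
    delays=PAPER_DELAYS_S,
    noise_frac: float = 0.02,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    label: str = "synthetic",
) -> IntensitySeries:
    """Four-curve Nz-exchange series with Gaussian noise.

    The noise standard deviation is ``noise_frac`` times the maximum
    simulated intensity, applied identically to all four curves; the sigma
    column records that true value.
    """
    if noise_frac < 0:
        raise InvalidInputError("noise_frac must be >= 0")
    rng = rng if rng is not None else stage_rng(seed, "exchange")
    clean = simulate_nz_intensities(model, delays, label=label)
    peak = max(
        clean.i_aa.max(), clean.i_bb.max(), clean.i_ab.max(), clean.i_ba.max()
    )
    sigma_val = noise_frac * peak
    n = clean.delays.size
    if sigma_val > 0:
        noise = rng.normal(0.0, sigma_val, size=(4, n))
    else:
        noise = np.zeros((4, n))
        sigma_val = max(1e-12, 1e-6 * peak)  # keep weights finite for fitting
    return IntensitySeries(
        delays=clean.delays,
        i_aa=clean.i_aa + noise[0],
        i_bb=clean.i_bb + noise[1],
        i_ab=clean.i_ab + noise[2],
        i_ba=clean.i_ba + noise[3],
        sigma=np.full(n, sigma_val),
        label=label,
    )


def gen_spr_isotherm(
    kd: float,
    rmax: float,
    concentrations=None,
    noise_frac: float = 0.02,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    variant: str = "synthetic",
) -> BindingIsotherm:
    """Langmuir isotherm with fractional Gaussian response noise.

    Default concentration series: six points geometric from 0.1x to 10x KD.
    Noise sd is ``noise_frac * rmax`` per point.
    """
    rng = rng if rng is not None else stage_rng(seed, "spr")
    if concentrations is None:
        concentrations = np.geomspace(0.1 * kd, 10.0 * kd, 6)
    conc = np.asarray(concentrations, dtype=float)
    resp = steady_state_response(kd, rmax, conc)
    resp = resp + rng.normal(0.0, noise_frac * rmax, size=conc.size)
    return BindingIsotherm(concentrations=conc, responses=resp, variant=variant)


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the sphere (normalized Gaussian triples)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def gen_rdc_set(
    tensor: AlignmentTensor | None = None,
    n_vectors: int = 30,
    noise_hz: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    first_residue: int = 1,
) -> tuple[BondVectorSet, RdcSet]:
    """Bond vectors uniform on the sphere plus couplings from a known tensor.

    Default tensor: axial magnitude 10 Hz, rhombicity ~0.3, randomly
    oriented by the construction of its off-diagonal elements.
    """
    rng = rng if rng is not None else stage_rng(seed, "rdc")
    if tensor is None:
        tensor = AlignmentTensor(np.array([-7.0, 20.0, 3.0, -2.0, 4.0]))
    residues = np.arange(first_residue, first_residue + n_vectors)
    vectors = BondVectorSet(residues=residues, vectors=random_unit_vectors(n_vectors, rng))
    rdcs = back_calculate(tensor, vectors)
    if noise_hz > 0:
        rdcs = RdcSet(
            residues=rdcs.residues,
            d=rdcs.d + rng.normal(0.0, noise_hz, size=rdcs.d.size),
            sigma=np.full(rdcs.d.size, noise_hz),
        )
    return vectors, rdcs


def lifetime_recovery_experiment(
    tau_ms: float,
    n_replicates: int = 100,
    noise_frac: float = 0.02,
    r1: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Recovered mean lifetimes (ms) from seeded generate-and-fit replicates.

    Each replicate simulates the four Nz-exchange curves at the default
    ten-delay sampling from a symmetric two-site model whose site lifetime
    is ``tau_ms`` (so k_ab = k_ba = 1/tau), adds fractional Gaussian noise,
    and refits with the symmetric estimator.  Returns the per-replicate
    recovered mean lifetimes; callers typically report the median.
    """
    k = 1.0 / (tau_ms * 1e-3)
    model = ExchangeModel(k_ab=k, k_ba=k, r1_a=r1, r1_b=r1, i0_a=1.0, i0_b=1.0)
    streams = np.random.SeedSequence([int(seed), _STAGE_KEYS["exchange"]]).spawn(
        n_replicates
    )
    out = np.empty(n_replicates)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        series = gen_exchange_series(model, noise_frac=noise_frac, rng=rng)
        fit = fit_nz_exchange(series, symmetric=True, seed=int(ss.generate_state(1)[0] % 2**31))
        out[i] = fit.tau_mean * 1e3
    return out


def kd_recovery_experiment(
    kd: float,
    rmax: float,
    n_replicates: int = 200,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Recovered KD values (uM) from seeded generate-and-fit replicates of
    a six-point 1:1 Langmuir isotherm with fractional response noise."""
    streams = np.random.SeedSequence([int(seed), _STAGE_KEYS["spr"]]).spawn(n_replicates)
    out = np.empty(n_replicates)
    for i, ss in enumerate(streams):
        iso = gen_spr_isotherm(kd, rmax, noise_frac=noise_frac,
                               rng=np.random.default_rng(ss))
        out[i] = fit_langmuir(iso).kd
    return out


def synthetic_template() -> CoordinateEnsemble:
    """Synthetic single-model template: an idealized protein helix plus a
    DNA-like double-helical backbone trace.

    Purely geometric stand-in used to exercise selection, superposition
    and RMSD code paths; it is not derived from any deposited structure.
    Protein chain A carries residues 80-148 with N, CA, C and CB atoms on
    an alpha-helical curve; DNA chains B and C carry residues 201-212 and
    213-224 with the six standard nucleic backbone atoms on opposed
    helical strands.
    """
    roster: list[tuple[str, int, str, str]] = []
    xyz: list[np.ndarray] = []

    def helix_point(i: float, radius: float, rise: float, per_turn: float,
                    phase: float = 0.0, offset=(0.0, 0.0, 0.0)) -> np.ndarray:
        ang = 2.0 * np.pi * i / per_turn + phase
        return np.array(
            [radius * np.cos(ang) + offset[0],
             radius * np.sin(ang) + offset[1],
             rise * i + offset[2]]
        )

    # protein alpha helix: 2.3 A radius, 1.5 A rise, 3.6 residues/turn
    for k, res in enumerate(range(80, 149)):
        ca = helix_point(k, 2.3, 1.5, 3.6)
        for name, delta in (
            ("N", np.array([-0.8, 0.5, -0.9])),
            ("CA", np.zeros(3)),
            ("C", np.array([0.9, -0.4, 0.8])),
            ("CB", np.array([1.2, 1.0, 0.2])),
        ):
            roster.append(("A", res, name, name[0]))
            xyz.append(ca + delta)

    # two opposed DNA-like strands: 9 A radius, 3.4 A rise, 10 nt/turn
    strand_info = [("B", range(201, 213), 0.0), ("C", range(213, 225), np.pi)]
    dna_atoms = (
        ("P", np.array([0.0, 0.0, 0.0]), "P"),
        ("O5'", np.array([0.6, 0.4, 0.5]), "O"),
        ("C5'", np.array([1.1, 0.8, 1.0]), "C"),
        ("C4'", np.array([1.5, 0.2, 1.6]), "C"),
        ("C3'", np.array([1.8, -0.5, 2.1]), "C"),
        ("O3'", np.array([2.2, -0.9, 2.7]), "O"),
    )
    for chain, resrange, phase in strand_info:
        for k, res in enumerate(resrange):
            base = helix_point(k, 9.0, 3.4, 10.0, phase=phase,
                               offset=(20.0, 0.0, -15.0))
            for name, delta, elem in dna_atoms:
                roster.append((chain, res, name, elem))
                xyz.append(base + delta)

    coords = np.array(xyz)[None, :, :]
    return CoordinateEnsemble(roster=roster, coords=coords, source="synthetic-template")


def gen_ensemble(
    template: CoordinateEnsemble | None = None,
    n_models: int = 20,
    jitter_a: float = 0.5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> CoordinateEnsemble:
    """Ensemble of ``n_models`` copies of a template with isotropic
    Gaussian coordinate jitter of sd ``jitter_a`` Angstrom per axis."""
    if jitter_a < 0:
        raise InvalidInputError("jitter must be >= 0")
    rng = rng if rng is not None else stage_rng(seed, "ensemble")
    if template is None:
        template = synthetic_template()
    base = template.coords[0]
    coords = np.repeat(base[None, :, :], n_models, axis=0)
    if jitter_a > 0:
        coords = coords + rng.normal(0.0, jitter_a, size=coords.shape)
    return CoordinateEnsemble(
        roster=list(template.roster), coords=coords,
        source=f"synthetic-jitter({jitter_a})",
    )
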