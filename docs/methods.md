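# Methods

## Two-site Nz-exchange kinetics

The longitudinal magnetization of a spin exchanging between bound states A
and B evolves as `dM/dt = -K M` with

    K = [[R1a + k_ab, -k_ba],
         [-k_ab,      R1b + k_ba]].

The four observables at mixing delay T are the elements of the propagator
`P(T) = expm(-K T)` applied to the initial magnetizations: auto peaks
`I_AA = P00·I0_A`, `I_BB = P11·I0_B`, cross peaks `I_AB = P10·I0_A`,
`I_BA = P01·I0_B`. The propagator is computed by an analytic 2×2
eigendecomposition — the discriminant `(K00−K11)² + 4·k_ab·k_ba` is
non-negative, so the eigenvalues are always real; a first-order expansion
handles the (measure-zero) degenerate case. Equivalence with direct ODE
integration is enforced by test oracles at 1e-8 relative tolerance. When
R1a = R1b the sums `I_AA + I_AB` and `I_BB + I_BA` decay as single
exponentials independent of the rates, a conservation law the tests check
at machine precision.

**Fitting.** All four curves are fit jointly by weighted least squares
(weights 1/σ² per point; unit weights with a warning when no σ is given),
with rates bounded at zero and three seeded multi-start restarts to avoid
local minima. By default a single R1 is shared between states: the same
nucleus in two closely similar complexes relaxes at nearly the same rate,
and four curves at realistic noise cannot robustly separate two R1 values
(splitting is available as an option). When the two sites are present at
equal concentration — the 1:2:2 protein:DNA:DNA mixing design — the
symmetric constraint `k_ab = k_ba` is appropriate and is what the recovery
experiments use.

**Lifetime convention.** "Mean lifetime" is reported as the
population-weighted site lifetime `τ = p_a/k_ab + p_b/k_ba`, which reduces
to 1/k under symmetric exchange where all common conventions (1/k_ab,
1/k_ex per site, weighted mean) coincide; τ_a = 1/k_ab and τ_b = 1/k_ba are
reported alongside. Parameter uncertainties come from the linearized
covariance by default, with seeded Monte-Carlo resampling as an option; the
two agree within ~50% at 2% noise in the tests.

The default delay list is the ten-point 11.9–211.8 ms sampling; the default
operating points are symmetric lifetimes of 40, 23, 66 and 34 ms with
R1 = 2 s⁻¹, equal initial magnetizations and 2% fraction-of-maximum
Gaussian noise.

## Lineshape simulation and population analysis

The absorption lineshape is `I(ν) = Re[1ᵀ A(ν)⁻¹ p]` with diagonal
`r2_j + k_out,j + i·2π(ν_j − ν)` and off-diagonals `−k_in`, where detailed
balance fixes `k_out,A = k_ex·p_b` and `k_out,B = k_ex·p_a`. Spectra are
normalized to unit area before measurement, so arbitrary-intensity inputs
give identical peak statistics. The default grid is 2048 points spanning
the resonances ± 20 times the larger Lorentzian width; peak positions use
parabolic refinement and FWHM linear interpolation of the half-height
crossings, so neither snaps to the grid.

Regime classification uses the angular frequency separation Δω = 2πΔν:
slow when `k_ex < Δω/5`, fast when `k_ex > 5Δω`. The factor of 5 is a
package choice (the equal-population coalescence point Δω/√2 always lands
in the intermediate band); it is exposed as a parameter. The corresponding
fast-exchange lifetime bound is `1/(5·2π·Δν)`. Site occupancies under fast
exchange follow from the averaged position,
`p_b = (ν_obs − ν_A)/(ν_B − ν_A)`; values outside [0, 1] are returned
flagged rather than clipped, since they indicate the fast-exchange
assumption failed.

## SPR Langmuir fits

Steady-state responses are fit unweighted to `R(c) = R_max·c/(K_D + c)`
with both parameters bounded positive; the fit warns when the top analyte
concentration is below the fitted K_D (R_max then rides the K_D/R_max
correlation). Synthetic isotherms default to six concentrations geometric
from 0.1× to 10× K_D with Gaussian noise of 2% of R_max — a realistic
dilution series for micromolar-affinity protein–DNA interactions. χ² is
reported as the raw sum of squared residuals; any presentation scaling is
left to the caller. Selectivity between DNA variants is the K_D ratio.

## RDC alignment tensor and Q factor

Each coupling contributes one linear equation `D = vᵀ S v` in the five
independent components of the traceless symmetric Saupe tensor, assembled
as rows `[y²−x², z²−x², 2xy, 2xz, 2yz]` and solved by SVD (least-norm).
The tensor is fit directly in Hz, absorbing the dipolar interaction
constant: the quality factor is scale-invariant, so physical-unit Da is
not needed. Geometry with design-matrix condition number above 1e8 (e.g.
near-parallel bond vectors) is rejected with the condition number in the
error. Q = rms(obs−calc)/rms(obs) by default; normalization by the rms of
the back-calculated couplings is available as an option. Principal-frame
quantities use |Szz| ≥ |Syy| ≥ |Sxx|, Da = Szz/2 and rhombicity
R = (2/3)(Sxx−Syy)/Szz ∈ [0, 2/3]. N–H bond vectors extracted from
coordinates lacking amide protons get an idealized in-plane H along the
external bisector of the CA–N and C(−1)–N directions (1.02 Å), with a
warning reporting how many were placed.

## Random-coil linker

RMS end-to-end distance of a freely jointed chain, `sqrt(C_∞ n l²)`, with
defaults frozen to C_∞ = 9.27, l = 3.8 Å (Cα–Cα) and a B-DNA rise of
3.4 Å/bp; all overridable. The base-pair span is reported fractional by
default with an optional floor.

## Ensemble RMSD statistics

Superposition is the Kabsch least-squares rigid-body fit restricted to
proper rotations (reflections rejected via the determinant correction);
tests pin it against a brute-force orientation-search oracle at 1e-3 Å.
To-mean statistics superpose every model on the evolving mean and iterate
until the mean shifts by <1e-6 Å (max 50 iterations); pairwise statistics
superpose each unordered model pair independently. Both modes are reported
because published precision values are quoted in both styles with similar
numbers. Atom classes follow the dominant conventions — protein backbone
N, CA, C; nucleic backbone P, O5', C5', C4', C3', O3'; "heavy" = all
non-hydrogen — and are configurable through the
`chain:start-end[:class]` selection syntax.

## Synthetic data

All generators draw from per-stage substreams of a single seed
(`SeedSequence([seed, stage_index])` with append-only stage indices), so a
given (seed, parameters) pair is byte-reproducible and new generators never
perturb existing fixtures. The coordinate-ensemble generator jitters a
template with isotropic Gaussian noise; the bundled template is a purely
synthetic idealized protein helix plus DNA-like backbone trace used to
exercise selection and superposition code paths — it reproduces no real
structure, so ensemble tests validate the statistics machinery (including
the analytic expectation `σ·sqrt(3(1−1/m))` for the per-model RMSD to the
mean), not any deposited ensemble's precision. What passing synthetic
tests show is that each estimator recovers the generating truth under the
noise model it assumes (independent Gaussian noise, exact model form);
real data add baseline distortions, correlated noise and model mismatch
that these fixtures deliberately do not emulate.

## Problem sizes and numerical choices

Recovery experiments use 100 replicates per exchange condition and
200 per SPR operating point, comfortably enough for stable medians of
estimators whose replicate-to-replicate scatter is a few percent. The
generator noise LLN check uses 300 replicates. Optimizer settings are
lmfit's `least_squares` (trust-region reflective) defaults throughout;
fits flag non-convergence as errors rather than returning silent results.
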