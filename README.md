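# mbdex

Quantitative analyses of how a methyl-CpG binding domain (MBD) moves between
recognition sites on DNA. The package implements, as a tested library plus a
thin CLI, the measurements that distinguish *intermolecular* exchange (the
protein dissociates and rebinds a different DNA molecule) from
*intramolecular* exchange (the protein transfers between sites on the same
molecule, i.e. facilitated diffusion):

- **Nz-exchange kinetics** (`mbdex.exchange`) — forward simulation and joint
  weighted least-squares fitting of the four auto/cross peak intensity curves
  of a two-site slow-exchange Nz (zz) experiment,
  `dM/dt = -K M` with `K = [[R1a + k_ab, -k_ba], [-k_ab, R1b + k_ba]]`,
  yielding exchange rates and mean site lifetimes τ.
- **Exchange lineshapes** (`mbdex.lineshape`) — two-site Bloch–McConnell 1D
  absorption lineshapes across the slow/coalescence/fast regimes, peak
  position and FWHM measurement, and site occupancies from fast-exchange
  averaged shifts (`p_b = (ν_obs − ν_A)/(ν_B − ν_A)`).
- **SPR affinities** (`mbdex.spr`) — steady-state 1:1 Langmuir fits
  `R(c) = R_max·c/(K_D + c)` and selectivity ratios between DNA variants
  (methylated, mismatched, hydroxymethylated, unmethylated CpG).
- **RDC tensor fits** (`mbdex.rdc`) — SVD fit of the Saupe alignment tensor
  to residual dipolar couplings against bond vectors,
  back-calculation, and quality factors
  `Q = rms(D_obs − D_calc)/rms(D_obs)`, with residue-range exclusion refits.
- **Random-coil linker reach** (`mbdex.linker`) — `sqrt(C_∞ n l²)` end-to-end
  length of a disordered polypeptide and its span in B-DNA base pairs.
- **NMR ensemble precision** (`mbdex.ensemble`) — Kabsch superposition and
  to-mean / pairwise RMSD statistics over multi-model PDB ensembles with
  protein/nucleic backbone selections.
- **Synthetic data** (`mbdex.synthetic`) — seeded generators emulating each
  experiment (noisy exchange build-ups, Langmuir isotherms, RDC sets from a
  known tensor, jittered coordinate ensembles), so the whole pipeline is
  testable without downloads.

## Worked example

Recover an exchange lifetime from synthetic data end to end:

```sh
mbdex generate exchange --seed 7 --tau-ms 40 --out demo/
mbdex fit-exchange demo/exchange.tsv --symmetric --seed 7
```

```json
{
  "k_ab_per_s": 24.239802650567572,
  "k_ba_per_s": 24.239802650567572,
  "tau_mean_ms": 41.25446128483992,
  "r1_a_per_s": 2.086298418670814,
  "residual_norm": 25.523972586279516,
  "n_points": 40,
  "uncertainties": {"k_ab": 0.396, "r1_a": 0.095, "i0_a": 0.0074, "i0_b": 0.0074}
}
```

The generator simulated a symmetric two-site system with a 40 ms site
lifetime (k = 25 s⁻¹) at ten mixing delays from 11.9 to 211.8 ms with 2%
Gaussian noise; the fit recovers τ = 41.3 ± 0.7 ms — the generating value to
within the noise — together with the shared longitudinal relaxation rate R1
≈ 2.1 s⁻¹. The same pattern works for the other stages (`generate spr` /
`fit-spr`, `generate rdc` / `fit-rdc`, `generate ensemble` /
`ensemble-rmsd`).

The linker calculation is a one-liner:

```sh
mbdex linker --n 280
```

```json
{"end_to_end_A": 193.59871900402646, "bp_span": 56.94079970706661, "n_residues": 280}
```

meaning a 280-residue disordered linker has an RMS end-to-end reach of
~194 Å, enough to span ~57 bp of B-form DNA — so two domains joined by it
can straddle well over 50 bp.

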