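# einspress

Analysis pipeline for **elastic incoherent neutron scattering (EINS) of
proteins under high hydrostatic pressure**: data reduction, model-free
mean-square-displacement (MSD) and master-curve analysis, global
two-state energy-landscape fitting, onset-temperature estimation, and
fractional-Brownian-diffusion (sub-diffusion) analysis — together with
a seeded generator of realistic synthetic elastic scans, so every
stage can be exercised and validated without instrument data.

## The science

EINS measures the elastic intensity I(q) scattered by the
(predominantly hydrogen) atoms of a protein sample within the
spectrometer's resolution time (~100 ps on a thermal backscattering
instrument such as IN13, q = 0.2–4.9 Å⁻¹). At low q the Gaussian
approximation holds,

    I(q) ≈ exp(−q² ⟨Δx²⟩),

so the slope of −ln I versus q² is the total MSD. Above an onset
temperature T_on ≈ 200 K proteins begin to jump among conformational
substates and the MSD rises steeply (the *protein dynamical
transition*). The substate landscape is summarized by a **two-state
(double-well) model**: each hydrogen occupies one of two wells a
distance *d* apart with free-energy gap ΔG = ΔH − TΔS. Its elastic
intensity is

    I(q) = exp(−⟨Δx²⟩₀ q²) · {1 − 2 p₁p₂ (1 − sin(qd)/(qd))},

with ⟨Δx²⟩₀ the MSD inside a single well and Arrhenius populations
p₂/p₁ = exp(−ΔG/RT). The total MSD decomposes as

    ⟨Δx²⟩_tot = ⟨Δx²⟩₀ + p₁p₂ d²/3.

The pipeline fits, at each pressure, **all** temperature curves of a
reduced scan simultaneously (a global fit sharing ΔH, ΔS/R and a
temperature-independent *d*, with one free ⟨Δx²⟩₀ per temperature).
Pressure-independent thermodynamics with a pressure-dependent *d*
signal that compression shrinks the structural distance between
substates without changing their energetics; an upward jump of *d*
above ~3 kbar reflects pressure-induced partial unfolding. As a
complementary, model-agnostic view, diffusion on the rugged landscape
is sub-diffusive, MSD(t) ~ D·t^α with α ≈ 1/2; at fixed resolution
time τ, a reduced MSD at equal α is a reduced effective D. The
`subdiffusion` module fits the power law and validates the exponent
with an exact fractional-Brownian-motion simulator (α = 2H).

## Worked example

```python
import einspress as ep

inst    = ep.InstrumentConfig(noise_rel=0.01, seed=1)   # IN13-like grid, 1% noise
profile = ep.PressureProfile()                          # d(P), harmonic baseline
scan    = ep.simulate_scan(20.0, inst, profile)         # 20 bar, 29 T x 24 q
reduced = ep.reduce_scan(scan)                          # normalize to the 20 K curve
report  = ep.global_fit(reduced)

print(f"dH   = {report.params.thermo.delta_h:.2f} +- {report.param_errs['dH']:.2f} kJ/mol")
print(f"dS/R = {report.params.thermo.delta_s_over_r:.2f} +- {report.param_errs['dS_R']:.2f}")
print(f"d    = {report.params.d:.3f} +- {report.param_errs['d']:.3f} A")

records = ep.decompose_msd(report)
onset   = ep.onset_temperature(records, seed=1)
print(f"T_on = {onset.t_on:.0f} +- {onset.t_on_err:.0f} K")
```

prints

```
dH   = 9.53 +- 0.19 kJ/mol
dS/R = 2.40 +- 0.09
d    = 1.511 +- 0.010 A
T_on = 180 +- 2 K
```

The generator's ground truth here is ΔH = 9.7 kJ/mol, ΔS/R = 2.5,
d = 1.5 Å: at 1% counting noise a single scan recovers the enthalpy
and entropy to a few percent and the well separation to ~1%, and the
piecewise-linear breakpoint of the total MSD locates the dynamical
transition near 180 K on this temperature grid. The fitted MSD at
300 K splits into 0.351 Å² of single-well motion plus an inter-well
term bringing the total to 0.470 Å².

## Command-line pipeline

The `einspress` entry point chains four stages, each driven by one
YAML config (all keys optional; unknown keys are rejected; every
output carries the resolved-config hash and seed, and identical
config + seed reproduce outputs byte for byte):

```sh
einspress simulate -c config.yaml   # synthetic scans + ground truth
einspress reduce   -c config.yaml   # cell subtraction, binning, 20 K normalization
einspress analyze  -c config.yaml   # MSD, master curves, global fits, onset, FBD
einspress report   -c config.yaml   # collated summary.json
```

Example config:

```yaml
seed: 5
paths:
  output_dir: out
reduction:
  bin_width: 10.0      # K
  transmission: 1.0    # cell transmission factor
generator:
  instrument: {noise_rel: 0.01, cell_level: 0.3}
  profile:
    pressures: [20.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0]
  thermo: {delta_h: 9.7, delta_s_over_r: 2.5}
  ramp: {enabled: true, n_sub: 3}     # emulate a slow heating ramp
```

`analyze` writes per-pressure Gaussian-MSD tables, normalized master
curves with their collapse metric, the d(P) table with a
pressure-independence check of the thermodynamics, per-pressure onset
temperatures, and the FBD block (fixed-τ MSD ratios plus an fBm
exponent self-check).

## Layout

| module | role |
| --- | --- |
| `forward_models` | populations, two-state intensity, MSD laws (pure functions) |
| `synthetic_data` | seeded IN13-like scan generator with cell background and d(P) |
| `reduction_io`   | TSV dialect, cell subtraction, binning, normalization |
| `model_free`     | Gaussian-approximation MSD, master curves, collapse metric |
| `two_state_fit`  | global fit, MSD decomposition, onset temperature, d(P) series |
| `subdiffusion`   | power-law fit, exact fBm simulator, fixed-τ MSD ratios |
| `cli`            | config handling and the four pipeline stages |

See `docs/methods.md` for the model conventions, generator design,
numerical choices and known limitations.
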