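# Methods

## Model and conventions

The package analyses elastic incoherent neutron scattering (EINS)
scans I(q; T, P) of hydrogenated protein samples. All mean-square
displacements (MSD) follow the convention

    I(q) = exp(−q² ⟨Δx²⟩)

with **no** 1/3 factor and **no** amplitude prefactor. Neutron
literature is split between ⟨u²⟩ and ⟨Δx²⟩ = ⟨u²⟩/3 conventions; every
MSD this package reads, fits or writes uses the exponent above, so
values are directly comparable to each other throughout.

The two-state model treats each hydrogen as occupying one of two wells
separated by a distance d (Å) with free-energy gap
ΔG(T) = ΔH − TΔS. Populations are Boltzmann/Arrhenius,
p₂/p₁ = exp(−ΔG/RT) with R = 8.314 J mol⁻¹ K⁻¹; ΔH is stored in
kJ/mol and ΔS as the dimensionless ΔS/R. ΔG may change sign at high
temperature; no clamping is applied (p₂ > p₁ is legal). The elastic
intensity is

    I(q) = exp(−⟨Δx²⟩₀ q²) {1 − 2 p₁p₂ [1 − sin(qd)/(qd)]},

and the total MSD (the q² → 0 slope of −ln I) is
⟨Δx²⟩₀ + p₁p₂d²/3. The sinc factor is evaluated with `np.sinc`,
which is exact and smooth at qd = 0, so no special series branch is
needed. A single fixed d is used — the model does not average over a
distribution of well separations.

## Reduction chain

1. **Empty-cell subtraction.** I_out = I_sample − tr·I_cell with
   transmission tr ∈ (0, 1], default 1 (instrument-dependent and not
   generally known; exposed as config). Uncertainties combine in
   quadrature. Negative differences are *kept* — clipping would bias
   subsequent least squares — and counted in the log.
2. **Temperature binning.** Ramp-mode curves are grouped into bins
   centred on multiples of the bin width (default 10 K, matching the
   typical presentation spacing of elastic scans), averaged point-wise
   with inverse-variance weights, and assigned the arithmetic mean
   temperature of their members.
3. **Normalization.** Every curve is divided point-wise by the curve
   at (nearest to) the 20 K reference. This pins I(q → 0) = 1 at all
   temperatures, which is why the global fit needs no free amplitude
   (a per-curve scale factor exists behind a flag for robustness).
   Uncertainties follow the quotient rule; the reference divided by
   itself is exact (perfectly correlated), so its sigma is set to 0,
   which also makes normalization exactly idempotent. After binning,
   the reference-matching tolerance widens from 2 K to half a bin
   width + 2 K, since the reference bin's mean temperature can sit
   anywhere inside its bin.

Subtraction precedes normalization (standard elastic-scan practice);
`reduce_scan` applies subtract → bin → normalize.

## Model-free analysis

*Gaussian MSD.* Weighted linear regression (statsmodels WLS, inverse
variance weights, intercept included) of −ln I on q² over q ≤ 2 Å⁻¹
by default. Points with non-positive intensity are excluded and
logged. For two-state curves the finite-q window biases the slope
slightly *below* the closed-form total MSD (the q⁴ coefficient of
−ln I, −2p₁p₂d⁴/120 + (p₁p₂d²/3)²/2, is negative at typical
parameters); the bias shrinks as the window closes and stays below 2%
at q ≤ 0.5 Å⁻¹ for representative parameters.

*Master curve.* Total intensity per temperature is the plain sum over
the q grid (a trapezoid mode differs only by fixed weights and
normalizes away), min-max normalized between the lowest and highest
*measured* temperatures: I_N = [I(T) − I(T_max)]/[I(T_min) − I(T_max)].
The collapse metric is the RMS deviation of the per-pressure I_N
curves from their across-pressure mean on a common temperature grid.
With pressure-independent thermodynamics the collapse is exact only to
leading order — different well separations leave a small residual in
the q-summed intensity (~0.005 RMS at the default geometry), below the
propagated 1%-noise level but not zero.

## Global two-state fit

Free parameters per pressure: ΔH, ΔS/R, d (shared across
temperatures) and one ⟨Δx²⟩₀ per temperature (default "free" mode; a
linear-in-T constrained mode exists for low-information scans). The
per-temperature choice is deliberate: single-well MSDs show their own
high-temperature anharmonicity, which a linear constraint would
silently absorb into the inter-well term. Residuals are
(model − data)/σ on intensities, not log-intensities, preserving the
noise model at large q where I is small. Positivity (and generous
upper bounds) are enforced through lmfit's bounded MINPACK
Levenberg–Marquardt, i.e. in a transformed parameter space.

The fit is restarted from a fixed 8-point grid,
d ∈ {0.5, 1.0, 1.5, 2.0} Å × ΔH ∈ {5, 15} kJ/mol (ΔS/R starts at 2);
single-well MSDs start from per-curve Gaussian fits. The converged
start with the lowest reduced χ² wins; if none converges the report
says so (`converged=False`), never a silent success. Everything is
deterministic given data and options.

*Identifiability.* d is only constrained when the upper well is
populated. The report flags `d_identifiable=False` when
max_T p₁p₂ < 10⁻⁴ or when the fitted inter-well term p₁p₂d²/3 at the
warmest temperature is smaller than twice its propagated uncertainty.
Truncating a scan to T ≤ 150 K inflates the relative d uncertainty by
an order of magnitude or more (surfaced, not hidden).

*Uncertainties.* Parameter errors come from the covariance of the
converged solution (scaled by reduced χ², lmfit default). Derived MSD
errors use first-order propagation with the analytic gradient through
the populations, using the full covariance when available.

*Pressure series.* Pressures are fitted independently; a row-level
`failed` flag keeps one bad pressure from aborting the series. The
thermodynamic pressure-independence check compares all parameter pairs
across pressures against their joint standard error at a family-wise
5% level (Bonferroni over the pair count) — with six pressures a naive
per-pair 2σ rule would flag pure noise roughly a third of the time.

## Onset temperature

Default method: exhaustive search over interior grid temperatures for
the best *continuous* two-segment piecewise-linear fit of total MSD
versus T, accepted only when it beats a single line (F-test at 5% with
an actual SSE reduction — an exactly linear input reports "none
detected" rather than an arbitrary breakpoint). Uncertainty is a
seeded residual bootstrap (200 replicates). The alternative
"threshold" method reports the first temperature where the inter-well
term exceeds 5% of the low-temperature harmonic extrapolation of the
total MSD (fitted to the first third of the grid). On the default
generator the breakpoint lands at 180 K: with a 10 K grid and an
Arrhenius-smooth crossover the best two-segment kink sits one
interval below the conventional ~200 K quoted for sharper-onset data;
both methods agree to within a few grid steps.

## Synthetic generator

The generator emulates a thermal-backscattering high-pressure
experiment: 24 q points spanning 0.2–4.9 Å⁻¹, 29 temperatures 20–300 K
(optionally as a jittered ramp with n sub-measurements per nominal
temperature), pressures 20 bar–5 kbar, resolution time τ = 100 ps
(metadata).

* **Signal**: two-state intensity with a harmonic single-well baseline
  ⟨Δx²⟩₀(T) = b(T − 20 K). The baseline passes through zero at 20 K
  because all data are normalized there (zero-point motion is absorbed
  by the normalization). The default slope b = 0.00125 Å²/K puts the
  single-well MSD at 0.35 Å² and the total near 0.47 Å² at 300 K —
  typical for a hydrated heme protein in this convention.
* **Thermodynamics**: defaults ΔH = 9.7 kJ/mol, ΔS/R = 2.5 — the
  low-pressure values for myoglobin in glycerol/water.
* **d(P)**: tabulated per pressure, 1.5 Å at 20 bar declining ~30% by
  2–3 kbar, jumping upward at the denaturation pressure (default
  3 kbar) and easing above — the qualitative morphology of
  pressure-induced partial unfolding. These are generator conventions
  (config), not measured truth.
* **Noise**: multiplicative Gaussian, I → I·(1 + ε), ε ~ N(0, 0.01²)
  by default, reflecting count statistics after normalization; the
  σ column carries noise_rel × the noiseless model intensity. The 1%
  level is a stated assumption chosen so that fitted-parameter scatter
  across seeds resembles quoted experimental uncertainties
  (±0.5 kJ/mol on ΔH ≈ 9.7, ±0.3 on ΔS/R ≈ 2.5).
* **Cell background**: additive, smooth in q, T-independent, 30% of
  the low-T sample signal. The sample-in-cell measurement carries its
  own counting noise on the cell contribution (a distinct seeded
  substream from the empty-cell scan), so subtraction leaves
  statistically correct residual noise instead of an artificial exact
  cancellation.
* **Seeding**: one master seed; every (pressure, temperature, role)
  triple gets its own `SeedSequence` substream, so any curve is
  independently reproducible and replicate experiments differ only by
  the master seed.

What the generator does *not* emulate: detector-geometry and
multiple-scattering effects, absorption, pressure-transmission-medium
artefacts, q-dependent resolution, or correlated detector noise.
Passing tests therefore demonstrate the *estimator's* correctness and
calibration under the stated statistical model, not robustness to
instrument systematics.

## Sub-diffusion / FBD

`fit_subdiffusion` is a weighted regression of ln MSD on ln t (slope
α, intercept ln D; D absorbs the dimensionality-dependent
proportionality constant, and the time grid is dimensionless
internally — τ = 100 ps enters only through reporting). The fBm
simulator draws exact fractional Gaussian noise by Davies–Harte
circulant embedding (Cholesky fallback for n ≤ 1024 if the embedding
fails), accumulates trajectories and averages squared displacements
over trajectories *and* time origins; its log-log slope converges to
2H. At H = 0.25 (200 trajectories × 1024 steps) the fitted exponent
reproduces α = 1/2 to better than ±0.05, operationalizing the
rugged-landscape exponent claim in-silico. Because an elastic scan
probes a single resolution time, the pipeline's FBD stage reports
fixed-τ MSD *ratios* between pressures (equal exponents make the
ratio a pure ratio of effective diffusion coefficients) plus the fBm
validation, rather than fitting α to measured time series.

## Problem sizes and defaults

The recovery experiments use the full default instrument (29 × 24
points) with 20 replicate seeds; the fBm validation uses 200 × 1024;
Monte-Carlo oracles in the tests use 10³–10⁴ draws. These sizes give
sampling errors comfortably below the tolerances they are tested
against. The pipeline's example configs in the test-suite use 15
temperatures and 2 pressures, sufficient for every stage to be
exercised end-to-end.

## Known limitations

* The two wells are an effective average over many conformational
  substates; no multi-well or hierarchical extension is provided, and
  denatured-state scans are fitted with the same two-state form.
* No quasi-elastic broadening, q⁴ (non-Gaussian cumulant) corrections,
  or quantum corrections at low temperature.
* ΔH/ΔS errors are fit covariances (scaled by reduced χ²); they do not
  include systematic contributions from, e.g., the cell transmission
  factor.
* The breakpoint onset estimator inherits the temperature grid's
  resolution; on a 10 K grid its bootstrap uncertainty is typically a
  grid step or less, and a smooth Arrhenius crossover can place the
  best two-segment kink a step or two below a visually judged onset.
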