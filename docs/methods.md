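# Methods

This note records the models implemented in `lipospin`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect results.

## Units and conventions

Magnetic field in gauss (positive-field convention, the low-field line of a
three-line spectrum is the "+" line), time in µs, temperature stored in
kelvin (inputs in °C are converted; anything below 200 K is tagged as a
rigid-limit measurement), curcumin in µM, lipid in mM, oxygen transport
parameter in µs⁻¹, correlation times in ns. All splittings are absolute
field distances.

## Equilibrium binding

Single-site association of the fluorophore (total `C_tot`, µM) with lipid
treated as independent sites at the total lipid concentration (`L`, mM,
converted to µM). The bound fraction is the exact root of the mass-balance
quadratic; a config switch (`binding.use_depletion`) selects the
no-depletion hyperbola `L/(L + K_d)` instead. Under the package's reference
conditions (2 µM probe, K_d ≥ 88 µM) the two agree to better than one
percentage point of bound fraction, so the choice is immaterial there; the
exact form is the default because it costs nothing and remains correct for
tighter binders.

Design choices, made where the formalism is genuinely open:

* **Stoichiometry.** Every lipid molecule is one independent site. Only
  relative K_d comparisons are made downstream, so any fixed
  lipids-per-site factor would cancel.
* **Leaflet accessibility.** No ×0.5 outer-leaflet correction is applied to
  the lipid concentration; users who need it can rescale their K_d.
* **Objective.** Plain least squares (Gaussian error), K_d shared across
  series, per-series `F0 ≥ 0` and `Fmax` free. The fit restarts from five
  log-spaced K_d initials spanning the lipid range plus the median lipid
  concentration and keeps the lowest χ²; standard errors come from the
  covariance at the optimum. A K_d pinned at a parameter bound triggers a
  warning and an `at_bound` flag rather than a silent return.

`affinity_ratio` propagates the two standard errors to the K_d ratio by the
delta method.

## Quenching localization

`remaining_percent = 100·F_sample/F_control` (scale-invariant by
construction). The classifier calls a depth *quenched* when remaining
≤ 100 − 20 percentage points, and the two depths *comparable* when they
differ by ≤ 5 points; both boundaries inclusive, both config-exposed
(`quenching.threshold_significant/threshold_equal`). These defaults
reproduce the expected classification for all four reference membrane
systems. Quencher concentration is single-point, so no Stern–Volmer slope
is attempted; incubation time is carried as metadata only. A sample
brighter than its control is flagged, not rejected.

## CW-EPR observables

### Fast motion (three-line spectra)

Line features are measured after optional Savitzky–Golay smoothing
(quadratic, default 11 points for this route): the three most prominent
maxima, each paired with the deepest following minimum; amplitudes are
refined max−min values and widths refined field distances, each extremum
position obtained from a least-squares parabola over the smoothing-window
footprint. Correlation times use
`τ_2B = k_B·ΔH₀·(√(h₀/h₋) − √(h₀/h₊))`,
`τ_2C = k_C·ΔH₀·(√(h₀/h₋) + √(h₀/h₊) − 2)` with
`k_B = k_C = 6.51·10⁻¹⁰ s/G` by default; both coefficients are first-class
config values (`calibration.k_B/k_C`) since published variants differ in
the constant. Negative τ (pathological amplitude ordering) is flagged,
never clipped. T-PC spectra are reported through `dh₊` and `h₀/h₋` instead
of τ, matching which parameter is meaningful for a headgroup probe.

### Slow motion (pseudo-powder spectra)

`2A_max` spans the leftmost significant maximum to the rightmost
significant minimum (prominence ≥ 2 % of the peak-to-peak span); `2A_min`
spans the deepest minimum below the spectrum midpoint to the highest
maximum above it — the central-line lobes fall on the *opposite* sides of
the midpoint and are thereby excluded geometrically rather than by a tuned
mask. The order parameter uses `A∥ = 2A_max/2`, the observed
`A⊥ = 2A_min/2` corrected by `+1.4·(1 − S_app)` G (the standard
compensation for the inner-splitting underestimate of powder patterns; a
switch disables it), and the polarity factor `a₀/a₀'` with
`a₀' = (A∥ + 2A⊥)/3`. Default tensor `(A_xx, A_yy, A_zz) =
(6.3, 5.8, 33.6)` G — typical doxyl-stearate values, config-exposed. If the
inner extrema are unresolved the result falls back to an `A∥`-only estimate
under the `a₀' = a₀` constraint and is flagged.

With the correction enabled, the exact isotropic identity `S = 0` at
`A∥ = A⊥ = a₀` does not hold (the correction contributes −1.4 G where the
powder bias it compensates is absent); measured S on a degenerate
`A∥ = A⊥` *spectrum* is ≈ +0.05 because convolution pushes the outer
extrema outward by about one Gaussian σ while the correction removes only
part of the inner bias. Both facts are asserted in the test suite at those
magnitudes.

`invert_order_parameter` solves the two-equation system (target S, polarity
factor pinned to 1) for `(A∥, A⊥_obs)` with a root finder; it is the
canonical way to choose generating splittings for a target S.

### Rigid limit

`2A_z` is the outer-extrema separation of the frozen-sample spectrum,
measured with the same machinery. Higher values mean higher local polarity.
The same tensor default is used at 120 K; low-temperature tensor shifts are
not modelled.

### Smoothing defaults per route

The extremum-search window scales with feature width: 11 points
(≈ 0.5 G at the default grid) for the sharp fast-motion lines, 31 for
slow-motion powder extrema, 61 for the broad rigid-limit edges. With these
choices, at 1 % relative noise over 50 fixed seeds the suite verifies:
low-field width `dh₊` stable to ±0.1 G, τ to 5 % relative, S to ±0.01,
`2A_z` to ±0.2 G. A single narrow window on the broad powder features
would miss the last two bands, which is why the defaults are per-route.

## Saturation recovery and oxygen transport

`fit_t1` fits `baseline − amplitude·exp(−t/T₁)` by nonlinear least squares,
initialized from the tail mean (baseline) and a log-linear regression of
the baseline-subtracted early signal (T₁). Inverted storage is handled by
letting the amplitude take either sign. A configurable initial-time cutoff
(`sr.t_cutoff_us`, default 0) drops early points; a fit whose T₁ exceeds
the time span is flagged truncated, and a span under 3·T₁ warns. Only the
single-exponential model is offered. `W = 1/T₁(air) − 1/T₁(N₂)` with
first-order SE propagation; W < 0 is flagged. No conversion of W to local
oxygen concentration or diffusion coefficient is attempted — W is
proportional to their product with an unknown constant. Depth profiles
order positions headgroup → C5 → C16 and expose pairwise differences and
control-vs-treated deltas (`b − a`, i.e. treated minus control) with
combined uncertainties.

## Synthetic generator

Purpose: every input the pipeline consumes, with stored ground truth and
bit-reproducible output (same parameters + seed ⇒ same bytes).

* **Fast-motion spectra**: three equal-area first-derivative Lorentzians at
  `B₀ ∓ a_N` (default `a_N` = 15.2 G); equal area makes amplitudes scale as
  `1/Γ²`, so a target (τ_2B, τ_2C) pair maps to a linewidth triple in
  closed form (`fast_motion_widths_for_taus`).
* **Powder spectra**: deterministic orientation averaging of
  `A(θ) = √(A∥²cos²θ + A⊥²sin²θ)` on a uniform cos θ grid (default 4000
  orientations — no Monte Carlo, so noise-free spectra are exactly
  reproducible), linear-weight deposition on the field grid, Gaussian
  convolution (default σ 1.25 G slow / 1.0 G frozen), numerical
  differentiation. The generator measures its own readout biases on the
  noise-free pattern (outer: ≈ −0.03 G; inner: ≈ −1.3 G at the defaults,
  the classic pseudo-powder underestimate the +1.4(1−S) correction exists
  for) and stores them with the record. The `*_for_observed` variants
  remove those biases by a fixed-point calibration against noise-free
  extraction, so a requested *measured* splitting (or 2A_z) is reproduced
  to < 0.02 G — the right construction when ground truth is defined on the
  observable, as in the order-parameter recovery study.
* **SR decays**: exact single exponential, 2048 points over 10·T₁ by
  default, additive Gaussian noise relative to the recovery amplitude;
  `gen_sr_pair` builds an air/N₂ pair from a W truth and a nitrogen T₁
  (default 5 µs, a typical membrane nitroxide value).
* **Titrations**: default lipid grid is the eleven-step two-fold dilution
  from 2 mM down to 0.0019 mM with 2 µM probe — the reference study
  conditions — three replicates, per-series multiplicative scale jitter
  (σ = 2 %) absorbed by the per-series nuisance parameters, additive noise
  of 1 % of the intensity span.
* **Quenching pairs**: control pinned at 100 units; sample =
  100·fraction + noise.

Noise is additive Gaussian scaled to max |signal|; there is no 1/f
component, baseline drift, phase error or g-tensor anisotropy, and no
stochastic-Liouville slow-motion simulation — the pseudo-powder pattern is
a geometric stand-in whose *derived* observables are controlled, not a
spectral-shape match to any instrument. Passing tests therefore demonstrate
correctness of the analysis pipeline under the stated noise model, not
robustness to instrument artifacts.

The shipped demo study (`lipospin demo` / `make_demo_dataset`) generates
four membrane compositions ± curcumin with the package's reference-table
truths (K_d 263/88/270/156 µM; remaining fractions 63/78, 62/64, 46/58,
55/71 %; τ pairs at 25 °C; S values 0.63–0.675; 2A_z and W profiles whose
stated deltas are 2.5/0.65/0.39 G, 0.85 G, 1.7 and 1.4 µs⁻¹). Headgroup
2A_z absolute values and the W endpoints are internally consistent choices
anchored to those deltas.

## Problem sizes and determinism

Spectra default to 2048 points over a 100 G sweep centered at 3350 G (an
X-band convention; sweep geometry is not a measured quantity). Statistical
suite sizes: 50 fixed seeds for the spectral recovery bands, 100–200
seeded replicates for K_d coverage (two-SE coverage ≥ 90 % asserted),
100 seeds for quenching unbiasedness. All randomness flows through
`numpy.random.default_rng(seed)`; derived seeds stay below 2³¹.

## Known limitations

* Pseudo-powder patterns have no motional narrowing between the fast and
  rigid limits; intermediate-regime spectra are out of scope.
* The order-parameter route assumes axially symmetric averaging and the
  default tensor; S for weakly ordered deep probes (bilayer center) is
  reported only when inner/outer extrema resolve, flagged otherwise.
* The binding model offers no Hill/multi-site or partition-coefficient
  formalism.
* Fluorescence quenching is steady-state only; lifetime-resolved analysis
  is not implemented.
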