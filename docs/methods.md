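# Methods

## Physical model

The sensor is a reflective fiber-optic Fabry–Pérot cavity: partial
reflections at the fiber end-face/medium and medium/mirror boundaries
interfere with phase φ = 4π·n·l/λ, where n is the refractive index of the
medium filling the cavity, l the geometrical cavity length and λ the vacuum
wavelength. The two-beam theoretical interferogram is T(λ) = 1 + cos(φ); it
is used both as the reference signal in feature extraction and as the core
of the synthetic generator. Multi-beam (Airy) corrections, polarization,
mirror tilt and cavity-length drift are deliberately outside the model: the
two-beam cosine is the signal model the feature mapping is defined against.

All wavelengths are handled in nm internally; the cavity length is accepted
in µm and converted once at the model boundary (l = 280 µm → 2nl ≈ 7.3·10⁵ nm
of round-trip optical path, fringe orders m ≈ 460–550 in the observed band).
Fringe maxima sit at λ_m = 2nl/m, giving a free spectral range near
λ² / (2nl) ≈ 3.3 nm at 1550 nm for n = 1.30.

## Synthetic measurement model

A synthetic trace is

P(λ) = E(λ)·[1 + V·cos(4π·n·l/λ)] + ε(λ)

with:

- **Envelope E**: Gaussian centered on the source wavelength (1550 nm) with
  FWHM equal to the source's spectral width (35 nm). The true
  superluminescent-diode shape is not critical; any unimodal envelope of the
  right width produces the same feature behavior, and the flat-envelope
  degenerate case is kept for testing against T(λ) directly.
- **Visibility V** (default 0.9956): multiplicative fringe-contrast loss
  summarizing mode mismatch, reflectivity imbalance and finite source
  coherence. The counted contrast (Imax − Imin)/(Imax + Imin) of the central
  fringe of a noiseless trace reproduces V to ~4·10⁻⁴ (the small deviation
  comes from envelope curvature across one fringe).
- **Noise ε**: zero-mean additive Gaussian with standard deviation
  `noise_sd` × peak power (default 1%), *correlated* over
  `noise_correlation_nm` (default 0.5 nm) along the wavelength axis,
  implemented as kernel-smoothed, variance-renormalized white noise. The
  correlation length models the effective resolution bandwidth/averaging of
  an optical spectrum analyzer trace: real OSA exports are smooth below that
  scale. This matters because the feature mapping counts *strict* local
  maxima — with per-sample white noise on a 2001-point grid the maxima count
  measures noise texture (hundreds of spurious peaks) rather than the
  ~12–15 physical fringes, which no measured trace exhibits. Setting
  `noise_correlation_nm = 0` recovers white noise for stress testing.
- **Dispersion**: liquids are named by their datasheet index at 589.3 nm
  (the *label* index, which also defines the class) but the physics should
  use the index at the 1550 nm operating wavelength. Per-liquid datasheet
  values at 1550 nm are not generally available, so the default mapping is
  the identity with an optional per-liquid override table
  (`LiquidPanel.operating_indices`). Labels always follow the label index,
  so an override changes the fringe physics, never the class.

The default study design is 21 liquids (1.30–1.50, step 0.01) × 10
replicates = 210 spectra on a 1530–1570 nm grid of 2001 points. The grid
density is a free acquisition parameter; tests that compare detected fringe
positions against the closed form use a denser grid so that grid
quantization (±half a step) stays below the asserted tolerance. Per-spectrum
noise seeds are spawned from one master seed via `numpy.random.SeedSequence`,
so a single integer reproduces the whole campaign bit-for-bit.

What the generator does *not* emulate: source ripple, wavelength-dependent
visibility, background reflections, detector nonlinearity, cavity-length
uncertainty between refills, and any liquid-specific dispersion. Passing
tests therefore demonstrate that the pipeline recovers class structure from
fringe geometry under the stated noise model — not that measured clinical
spectra will classify equally well.

## Feature mapping

Each spectrum, paired with the theoretical reference generated from its own
cavity model, yields one 18-slot row (F1–F17 features, F18 target):

- **Threshold filter (F3, default 0.05)**: samples below
  threshold × global maximum are flagged out of the maxima analysis (power
  values are retained; the global maximum is unchanged). This removes the
  fringe troughs and envelope tails where noise dominates. A threshold of
  exactly 0 retains every sample.
- **Local maxima (F1)**: interior retained samples strictly greater than
  both retained neighbors; plateaus count once at their leftmost point.
  Deliberately a plain neighbor scan (no prominence or width criteria) — the
  threshold filter is the only smoothing step.
- **Spacing statistics (F5–F8)**: mean/max/min/median of consecutive-maxima
  wavelength differences. With fewer than two maxima all four fall back to a
  sentinel 0 and the event is logged; the study design never produces such
  spectra, but file-supplied ones might.
- **Amplitude factor (F4)**: f = ssmax / global max, the ratio of the
  reference's maximum to the spectrum's. f × global max recovers ssmax
  exactly (a grid quantity marginally below the analytic peak of 2).
- **Distortion (F9)**: D = |(1 − area_exp·f)/area_sym| with both areas by
  composite Simpson quadrature. Signals on different grids are linearly
  resampled to a shared uniform odd-count grid over the overlap window first
  (composite Simpson requires uniform spacing). The formula is applied
  literally in its printed asymmetric form — area_exp·f is compared against
  1, not against area_sym — so even a self-comparison yields
  D = |1 − A|/A ≈ 0.975 for A ≈ 40 nm·units; no dimensional "correction" is
  applied. D is consumed as an opaque distortion score by the classifiers.
- **Axial shift (F10)** and **RMSE (F11)**: global-maximum wavelength
  difference (experimental − reference, ties broken toward the lowest
  wavelength) and the root-mean-square of f·experimental − reference (the
  rescaling puts F11 in reference units; same-grid signals are differenced
  pointwise).
- **Geometry slots**: F2 global maximum, F12 cavity length (µm), F13/F14
  window bounds, F15 power amplitude (max − min), F16/F17 peak wavelengths
  of spectrum and reference. F17 is reported in nm like every other
  wavelength feature.

Rows are all-or-nothing: any sub-operation failure rejects the spectrum
rather than emitting a partial row.

## Labeling and splits

Class 0 (healthy analog) for label index ≤ 1.38, class 1 (cancer analog)
for ≥ 1.39, with ε = 10⁻⁶ guarding float representation of the 0.01 grid;
indices outside [1.30, 1.50] are rejected. The default design gives
90 healthy / 120 sick (43% / 57%).

A stratified 20% validation split is taken before cross-validation; the
remaining rows get a stratified k-fold plan (k = 3 by default — small
enough for stable folds on 168 rows, and odd-k alternatives 5/7/9 behave
equivalently on this design). The default split is **row-level** stratified,
which mirrors the standard stratified-sampling protocol and keeps the split
arithmetic exact (42 validation rows = 18 healthy + 24 sick); because
replicates of one liquid then appear on both sides, validation scores
include replicate-similarity leakage. `group_aware=True` holds out whole
liquids instead (class-stratified at the liquid level), which removes that
leakage at the price of rounding to whole liquids and of occasionally
holding out a boundary liquid whose class genuinely cannot be inferred from
its neighbors. Both modes are seed-deterministic.

## Classifiers and evaluation

Four families with the study hyperparameters: random forest (100 trees,
Gini, min_samples_split 2, min_samples_leaf 1), gradient-boosted trees
(gbtree booster, learning rate 0.3, min split loss 0, max depth 6, uniform
sampling), Gaussian naive Bayes (no priors, var_smoothing 1e-9), and a
feed-forward network with 32/16/1 units, ReLU hidden activations, a sigmoid
output unit and 200 training epochs (the architecture is dense as printed;
features are standardized inside this family only — trees and naive Bayes
consume raw rows). Tree and Bayes families are exactly seed-deterministic;
the neural family is seeded but only tolerance-tested.

Evaluation uses cancer-positive confusion matrices (TP = cancer classified
as cancer) and accuracy, precision, recall, F1. Undefined metrics (zero
denominator) are reported as NaN with a warning, never silently as 0. Each
CV fold is scored both on its held-out fold (the default reporting
convention) and on its own training rows (`fold_score: train`), since
either convention is defensible for fold-level reporting; the validation
row always comes from a model retrained on all training rows. Wall-clock
fit/predict times are logged per classifier but never asserted — they are
hardware-dependent.

## Numerical choices and degenerate inputs

- Global-maximum ties break toward the lowest wavelength, deterministically.
- All-zero spectra, zero experimental maxima, non-overlapping wavelength
  windows and single-class training sets raise typed errors
  (`DegenerateInputError`, `IncompatibleDomainError`, ...) rather than
  producing sentinel rows.
- Spectrum files are two-column text (wavelength nm, power), '#' comments,
  comma or whitespace delimited; rows are sorted by wavelength on read.
- Pipeline stages log row counts in/out so a discrepancy is localizable to
  the stage that introduced it; stage failures abort with a stage-tagged
  error.

## Known limitations

- The identity label→operating index mapping understates dispersion; with
  real Cargille datasheet values the fringe features would shift slightly
  (monotonically), which the classifiers tolerate but the closed-form tests
  would need the override table for.
- Validation scores under the default row-level split are optimistic for
  unseen liquids; use `group_aware=True` to estimate interpolation
  performance instead.
- The noise model is additive and stationary; multiplicative (signal-
  proportional) noise and slow baseline drift are not modeled.
- The neural family exists for protocol completeness; with 17 tabular
  features and 168 training rows it has no advantage over the classical
  families and its scores vary with initialization within a few percent.
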