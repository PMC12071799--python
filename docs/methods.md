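# Methods

`witherfuse` models the first stage of black-tea manufacture: leaves
wither for ~12 h while their moisture content (MC, mass fraction of
water) falls from ~75% through three practical classes — insufficient
(> 62%), moderate (58–62%, boundaries inclusive), excessive (< 58%).
The package predicts MC from two complementary sensors, near-infrared
(NIR) absorbance spectra (900–1700 nm; internal chemistry) and RGB
leaf images (external appearance), and compares four ways of fusing
them. Because no public withering dataset exists at this scale, a
seeded synthetic generator defines the benchmark conditions and plants
a known ground truth that the selection algorithms can be scored
against.

## Synthetic withering data

**MC trajectory.** Thin-layer exponential drying law
`mc(t) = mc_inf + (mc_0 − mc_inf)·exp(−k·t)` with defaults
`mc_0 = 0.75`, `mc_inf = 0.50`, `k = 0.15 h⁻¹`, sampled hourly at 13
time points with 15 replicate samples each (195 samples) and replicate
jitter of sd 0.004 — roughly the heterogeneity of a turned withering
trough plus moisture-analyzer error. The curve must start above 0.62
and end below 0.58 so all three degree classes occur; configurations
that cannot are rejected.

**Spectra.** 760 channels evenly spaced on 900–1700 nm. Each spectrum
is a smooth quadratic baseline plus Gaussian absorption bands: O–H
water bands near 970/1190/1450 nm whose depths increase with MC, and
C–H dry-matter bands near 1200/1700 nm whose depths increase as MC
falls; widths 16–38 nm so neighbours overlap as in real leaf NIR.
Band depths are affine in MC. Three imperfections are layered on top,
each with its own seeded substream:

* *scatter*: per-spectrum offset and gain, both N(0, 0.05) — the
  additive/multiplicative path-length effects SNV is designed to
  remove;
* *channel noise*: iid N(0, 0.001) absorbance;
* *response deviations*: a per-sample NIR deviation (sd 0.008 MC
  units) shared across bands, plus per-band deviations (sd 0.005)
  reflecting that water and catechin chemistry do not track MC
  identically.

The response deviations are what keep the synthetic problem honest:
without them every sensor is a perfect MC encoder, all models saturate,
and fusion cannot help. With them the single-sensor models land at
RPD ≈ 5–8 and multi-sensor fusion has something real to add. The
generator records the channel nearest each informative band centre as
ground truth for recovery tests.

**Images.** An elliptical leaf mask on a neutral background. The leaf
base colour interpolates from bright green (RGB 72/186/78 at MC 0.80)
to dark green (30/92/44 at MC 0.45) — the visual transition of
withering — and a band-limited speckle field (Gaussian-filtered white
noise, σ = 1.5 px) adds surface-wrinkling texture whose amplitude
grows from 4 to 30 gray levels as the leaf dries. The image reads MC
through its own response deviation (sd 0.012), slightly worse than the
NIR sensor, matching the usual ordering of the two technologies.

**What the generator does not emulate.** No Beer–Lambert or
radiative-transfer realism, no instrument specifics (exposure,
gratings, illumination geometry), no leaf-shape variation, and the
replicate samples of one hour are exchangeable. Passing benchmarks
here show the pipeline's statistical machinery works under a
controlled, known-truth regime — not that the specific RPD values
would transfer to a physical withering trough.

## Preprocessing and features

Replicate scans are averaged channel-wise first; SNV (subtract row
mean, divide by row sd with n−1) is then applied to the full block.
SNV exactly removes the affine scatter model (`snv(a + b·x) = snv(x)`),
which the tests assert as an identity.

Eighteen image descriptors in a fixed order: 12 color (R, G, B means;
H, S, V; CIELAB L*, a*, b*; excess green 2G−R−B; R/G; hue angle
hab* = atan2(b*, a*)) and 6 histogram-statistical texture features
(mean gray m, sd δ, smoothness r = 1 − 1/(1 + σ²/(L−1)²), third moment
μ₃/(L−1)², uniformity U = Σp², entropy e = −Σp·log₂p) on the
0.299/0.587/0.114 luminance quantized to 256 levels. Color conversions
are computed from the in-mask **mean RGB** — a deliberate convention
(per-pixel conversion then averaging is a different estimator); the
oracle tests pin it. Achromatic colors (|a*|, |b*| < 0.01) get
hab* = 0. Features are min–max normalized with statistics from the
calibration rows only, and screened by Pearson correlation with MC at
an **inclusive** cutoff |r| ≥ 0.6 (the boundary case r = 0.6 is
retained). p-values (t transform, n−2 df) are reported but retention
uses only |r|.

## Wavelength selection

All three algorithms score candidate subsets by k-fold RMSECV of a
PLS1 model (NIPALS; coefficients for all component counts in one
pass). One fold assignment per selection run is reused across all
subset evaluations (common random numbers), so comparisons between
subsets are not confounded by fold luck.

* **CARS** — 50 Monte-Carlo runs, 5-fold CV. Each run fits PLS on a
  random 80% sample subset, ranks live variables by the
  **standardized** coefficient |b_j|·sd(x_j) (raw |b_j| rewards
  small-scale channels: on unscaled blocks it is inversely
  proportional to channel scale and noise channels outrank signal —
  measured 2/20 vs 19/20 planted recovery), shrinks to the
  exponentially decreasing ratio r_i = a·e^(−k·i) (r₁ = 1,
  r_N = 2/p), then resamples with replacement proportionally to the
  weights (duplicates collapsed). Minimum-RMSECV run wins; earliest
  run breaks ties.
* **VISSA** — weighted binary matrix sampling, max 15 latent
  variables, 5-fold CV. Inclusion weights start at 0.5; each
  iteration draws sub-models with per-variable inclusion probability
  w_j, keeps the best 5%, and resets w_j to the elite inclusion
  frequency — accepted only while the elite-mean RMSECV improves.
  Selected: w_j ≥ 0.5.
* **VCPA-IRIV** — 10 CV groups, max 5 latent variables. Stage 1
  shrinks the space along the same EDF form, with random exact-half
  sub-models voting for variables (top 10% of sub-models vote); the
  schedule floors at 10% of p (min 5) rather than 2, so stage 2
  receives a meaningful space. Stage 2 (IRIV) repeatedly classifies
  each survivor by comparing RMSECV distributions of sub-models
  including vs excluding it (Mann–Whitney at α = 0.05 plus the sign
  of the mean difference) and drops variables whose inclusion does not
  help; here sub-models use independent Bernoulli(0.5) inclusion,
  because the exact-half design degenerates to single-variable models
  when few variables remain and then measures "best single variable"
  instead of marginal value. Backward elimination finishes.

Compression rate is 100·(1 − n_selected/n_original), rounded half-up
to one decimal.

**Recovery benchmark design.** The planted-recovery simulations use 50
channels with three 6 nm-wide bands centred exactly on grid channels
and band-specific deviations (sd 0.02). Narrow on-grid bands matter:
wide bands make neighbouring channels collinear with the planted one,
and a shared MC signal makes the three bands mutually redundant — in
either case "every planted channel selected" is not a well-posed
criterion for parsimonious selectors. The VCPA-IRIV sub-model
population is 200 in these simulations (canonical default 1000,
configurable): 100 makes the stage-1 votes and rank tests unreliable.

**Null control.** The no-enrichment test permutes the response *and*
shuffles each channel's rows independently. Permuting y alone is not a
valid null here: the planted trio stays mutually correlated, and
cross-validation legitimately prefers such low-complexity collinear
groups even without signal, so the hypergeometric baseline (which
assumes exchangeable channels) would be exceeded for a real
statistical reason.

## Fusion and modeling

* **Low level** — column-wise concatenation (760 + 18 = 778), full
  per-column provenance.
* **Middle level, PCA** — per-sensor PCA with centering statistics
  from calibration rows only; the per-sensor component count is chosen
  by scanning k = 1…18 with an SVR model and taking the k with the
  best prediction-set RPD (ties → smallest k), then the chosen score
  sets are concatenated.
* **Middle level, variable selection** — selected spectral channels
  (from SNV spectra, calibration rows) concatenated with the screened
  image features, spectra first.
* **High level** — ordinary least squares of the actual calibration MC
  on the per-sensor SVR calibration predictions,
  y = b + k₁x₁ + k₂x₂, applied unchanged to prediction-set
  predictions. No internal cross-validation layer: the stacking is fit
  on in-sample predictions, accepting the optimistic-calibration
  caveat that design carries. Least squares guarantees the stacked
  calibration RMSE never exceeds any single sensor's best affine
  recalibration; a test asserts this numerically.

The regressor throughout is ε-SVR with RBF kernel and ε = 0.01,
parameterized by the libsvm-style cost/width pair (c, g) that NIR
calibration studies conventionally report. (c, g) are tuned per model on
a log₂ grid 2⁻⁸…2⁸ (step 2²) by 5-fold CV RMSE on the calibration
set; ties prefer smaller c, then smaller g. The 3:1
calibration/prediction split is a seeded random draw stratified by
withering hour (largest-remainder allocation, singleton strata go to
calibration); an every-4th-sample rank-order split is available behind
a flag for sensitivity checks. Metrics: Rc/Rp (Pearson,
measured vs predicted), RMSEC/RMSEP, and RPD = sd(prediction-set
reference MC, n−1)/RMSEP, reported as +inf with a warning when
RMSEP = 0.

## Problem sizes and numerical choices

The full experiment grid runs at study scale (195 × 760) with
sub-model populations sized for a single desk CPU: VISSA 150
sub-models per iteration, VCPA 100 per EDF run (both configurable;
canonical populations are 1000). The 20-seed fusion-ordering
comparison runs at 65 samples × 80 channels with VISSA at 60
sub-models. Degenerate inputs fail loudly: constant spectra rows name
the offending sample, constant features map to 0 with a warning,
rank-deficient PLS folds truncate the component count with a warning,
collinear stacking designs fall back to the minimum-norm solution.
All stochastic stages draw from independent substreams of one global
seed; identical configurations produce byte-identical datasets and
identical selections.

## Known limitations

* The generator's statistical contracts (monotone color/texture in MC,
  affine band depths, SNV-removable scatter) are the *only* realism
  guaranteed; absolute metric values on synthetic data exceed what
  field data would give.
* On field data, PCA fusion is often the weakest strategy because the
  leading PCs need not respond to MC; on this synthetic benchmark the
  dominant variance directions do align with MC, so PCA fusion
  performs on par with the other strategies here.
* High-level stacking can inherit optimism from in-sample calibration
  predictions, by construction.
* Selection-algorithm hyperparameters beyond the core settings
  (sampling ratio, elite fractions, α, shrink floors) are configurable
  defaults taken from the canonical algorithm descriptions, and are
  logged in every `SelectionResult`.
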