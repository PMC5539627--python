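# Methods

This note documents the models and procedures `nircal` implements, the
choices made where the conventions admit more than one reading, and what
the synthetic data generator does and does not emulate.

## Spectral model and pretreatments

Spectra are absorbance, log(1/R), on an evenly spaced wavelength grid
(default 1100–2000 nm in 2 nm steps, 451 points). Replicate scans of a
sample are arithmetic-averaged before any modelling; because averaging is
linear it commutes with the linear pretreatments, which the tests assert
numerically.

A treatment is a scatter correction followed by a derivative/smoothing
stage, named `"<scatter> d,g,s1,s2"`:

- **MSC.** Each spectrum *x* is regressed on a reference spectrum,
  *x* ≈ *a* + *b*·ref, and corrected to (*x* − *a*)/*b*. The reference is
  the mean spectrum of the calibration set, frozen at fit time and reused
  unchanged on validation spectra. (An instrument-supplied reference would
  also fit this interface; the mean spectrum is the common default.)
- **SNV.** Each spectrum is centred and scaled to unit standard deviation.
  The sample (P−1) divisor is used; this is stated so the unit tests can be
  exact (e.g. [1, 2, 3] → [−1, 0, 1]).
- **DT (detrend).** A least-squares quadratic in wavelength is subtracted
  per spectrum. Order 2 is the standard detrend definition and is fixed.
  **SNV–DT** applies SNV first, then DT.
- **Derivative `d,g,s1,s2`.** Norris gap–segment convention: an s₁-point
  running mean, then *d* successive gap differences *x*[i+g] − *x*[i], then
  an s₂-point running mean. `s=1` means no smoothing, `d=0` no derivative.
  The gap difference is not divided by the gap width, so the first
  derivative of a line with slope *m* is the constant *m·g·Δλ*. Points
  consumed by the windows are dropped rather than padded — the output grid
  shrinks by (s₁−1) + d·g + (s₂−1) points and is annotated with the centre
  wavelength of each surviving window; padding would fabricate boundary
  values that the derivative treatments then amplify.

Scatter correction runs before the derivative. Treatment strings name the
scatter method first and this is the conventional order; it is fixed in the
`Preprocessor` but each primitive is also exported separately for
non-default compositions.

## Modified PLS

`MPLSRegression` is NIPALS PLS1 with per-wavelength residual
standardization. X and y are mean-centred (no autoscaling of X — spectral
channels share units and autoscaling would inflate noise-only
wavelengths). For each factor: the weight vector is **w** ∝ Eᵀf, scores
t = E**w**, X-loadings **p** = Eᵀt/tᵀt, y-loading q = fᵀt/tᵀt, followed by
deflation of E and f. The *modified* step: before extracting the next
factor, every column of the deflated E is divided by its standard
deviation. These scale vectors are stored per factor so prediction can
replay the identical path on new spectra. Only X-residuals are rescaled;
y-residuals are left alone — rescaling a single centred y column would
merely renormalize it and change nothing identifiable.

Two predictors are exposed: the factor-path replay, and the collapsed
affine form β₀ + Xβ obtained by pushing the coordinate basis through the
replay. They are the same map up to floating-point error (asserted at
1e−8), and with standardization disabled the estimator agrees with
scikit-learn's `PLSRegression(scale=False)` to better than 1e−6 — that
library serves as the independent oracle for the unscaled limit, never as
the implementation.

Degenerate inputs: a residual standard deviation below 1e−10 of the
largest is clipped before rescaling, and a weight or score norm collapsing
to zero raises a rank-deficiency error naming the achievable factor count.

## Cross-validation and factor selection

The calibration set is randomly partitioned into seven size-balanced
groups (no contiguity structure; seeded). For each held-out group the
*entire* pipeline is refitted on the remaining groups — including the MSC
reference and the MPLS centres/scales — so the held-out predictions carry
no leakage; the permutation test in the suite checks this. SECV at each
candidate factor count is the plain RMS of held-out residuals (the
root-mean-square error of cross-validation); SEC uses the
degrees-of-freedom denominator N − k − 1. The chosen factor count
minimizes SECV, ties resolved toward fewer factors; a `fixed` policy is
available for reproducing a published factor count (the defaults carry 7
or 8 per constituent). Cross-validation groups are re-randomized per
constituent from the run seed.

## Outlier screening

Screening is a single sequential pass (an iterative mode exists behind a
flag but is off by default):

1. **H stage.** PCA scores of the treated calibration spectra (k = the
   model's factor count) give the normalized Mahalanobis statistic
   H = d²/k, whose calibration-set mean is ≈ 1; samples with H **strictly
   greater than** 3 are removed before any regression.
2. **T stage.** The survivors are cross-validated and
   T = |y − ŷ_cv| / SECV computed; samples with T strictly above 2.5 are
   removed. SECV rather than SEC is the scale because the residuals are
   themselves cross-validated; the scale is configurable.

The report preserves the count identity N = retained + removed-by-H +
removed-by-T. Note that MSC largely *corrects* a purely multiplicative
spectral outlier — that is what it is for — so H screening is most
sensitive on treatments that do not rescale per spectrum (e.g. detrend
only), which is what the sensitivity tests use.

## Assay calculations

Standard curves are ordinary least-squares lines of response on
concentration (≥ 3 distinct points). Quantification inverts the curve and
scales by the extract dilution (default 1:100) and mass basis; TEAC
inverse-evaluates the Trolox curve at the sample's ABTS % inhibition,
flagging extrapolation. The β-carotene bleaching metric is
100·(A₀ − A₁)/A₀, the standard form of that assay: scale-invariant,
monotone decreasing in A₁, 100% when the signal is fully protected. The
ABTS kinetic series (one read per minute for 10 min) is summarized by the
endpoint read (configurable minute, default 10).

## Synthetic data

`simulate_dataset` produces N = 99 samples × 3 replicates by default. Each
clean spectrum is a fixed broad **matrix background** (four wide Gaussian
bands, peak 0.8 AU) plus small analyte contributions: 0.15·u_f·flavone +
0.15·u_fn·flavanone + 0.10·u_m·wax, with latent levels u ~ U(0,1), plus a
per-sample quadratic baseline. Each replicate then gets multiplicative
scatter (slope 0.9–1.1, offset ±0.05) and white noise of sd 0.005 AU.
Two structural choices matter:

- The **dominant common background** makes the per-spectrum scale estimated
  by MSC/SNV reflect scatter rather than composition — the regime in which
  those corrections are well-posed for a ground-powder reflectance
  measurement. Without it, normalization destroys the concentration signal.
- The **analyte bands are narrow (~20 nm)** relative to the background
  (60–150 nm), so gap derivatives flatten the background while retaining
  analyte signal — the regime derivative pretreatments exist for.

Reference chemistry: quercetin- and rutin-equivalents are affine in the
same flavone latent (two standards quantifying one class; the rutin copy
carries latent noise of sd 0.02), pinocembrin in the flavanone latent, and
the two antioxidant measures are clipped noisy mixtures of the flavonoid
latents (ABTS weights 0.7/0.3, inhibition 0.5/0.5, latent noise sd 0.03) —
antioxidant capacity tracking phenolic composition. Value ranges span the
pooled Spanish/Chilean observations (quercetin 0–63.3 mg/g, rutin
0–161.1 mg/g, pinocembrin 27.0–149.7 mg/g, ABTS 641.2–8215.4 nmol
Trolox/mg, inhibition 22–88%). A three-cluster regional mode
(Galicia / Castilla y León / Bio-Bio latent means) exists for
variability demonstrations but is off by default.

What the generator does **not** emulate: instrument line shape and
wavelength registration error, detector heteroscedasticity, moisture and
particle-size effects beyond the multiplicative/additive scatter model,
non-linear detector response, and any real covariance structure among
propolis constituents beyond the linear linkage above. Tests passing on
these data therefore certify the *algorithmic* pipeline — preprocessing
algebra, factor extraction, screening logic, statistics — not predictive
performance on real propolis.

`inject_outliers` creates spectral outliers by inflating the scatter slope
tenfold and chemical outliers by replacing a sample's reference value with
that of the most distant sample in that constituent (so exactly the
labelled samples are mislabelled, which keeps sensitivity scoring exact).

## Problem sizes and determinism

The repeated-simulation checks (SECV > SEC frequency, screening
sensitivity) use 70-sample datasets over 50–100 seeds, enough to estimate
the relevant frequencies to a few percent while keeping a full suite run
in tens of seconds. Every stochastic step — simulation, the 70/29 split,
CV grouping, outlier injection — draws from `numpy.random.default_rng`
seeded from the run seed (per-constituent offsets for CV), so reports are
byte-identical across reruns with the same configuration.

## Known limitations

- MPLS is implemented for a single response (PLS1); multi-response
  calibration is out of scope.
- The JCAMP-DX reader covers single-spectrum AFFN `XYDATA=(X++(Y..Y))`
  files only (no compressed DIF/DUP forms).
- No wavelength selection, PCR/SVM alternatives, or robust-regression
  outlier handling; H/T screening is the only sample-elimination
  mechanism.
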