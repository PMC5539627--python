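# nircal

NIR chemometric calibration of propolis flavonoid content and antioxidant
capacity.

Propolis — the resinous material honeybees collect from plant exudates —
owes its antioxidant and antimicrobial value largely to its flavonoid
fraction. The reference assays for that fraction (AlCl₃ complexation for
flavones/flavonols against quercetin or rutin standards, DNP reaction for
flavanones/dihydroflavonols against pinocembrin, ABTS radical scavenging
expressed as Trolox equivalents, and β-carotene/linoleic-acid bleaching
expressed as % inhibition) are slow, destructive and solvent-hungry.
Near-infrared (NIR) reflectance spectroscopy of the ground raw material,
recorded as log(1/R) on a 1100–2000 nm grid at 2 nm steps, offers a rapid
non-destructive alternative once a multivariate calibration links the
spectra to the reference chemistry.

`nircal` implements that calibration workflow end to end, for analysts
building or auditing NIR calibrations of this kind:

- **Spectral pretreatment** — multiplicative scatter correction (MSC),
  standard normal variate (SNV), quadratic detrend (DT), SNV–DT, and
  Norris gap–segment derivatives named by the four-digit code `d,g,s1,s2`
  (derivative order, gap, first and second running-average smoothing), so
  treatment strings such as `"Standard MSC 2,4,4,1"` are accepted verbatim.
- **Modified partial least squares (MPLS)** — NIPALS PLS1 in which, after
  each factor is deflated, the spectral residual at every wavelength is
  divided by its standard deviation before the next factor is extracted.
  The fitted factor path collapses to the affine form
  *y* = β₀ + β₁X_λ₁ + β₂X_λ₂ + … + βₙX_λₙ used for reporting influential
  wavelengths. With the standardization disabled the estimator reduces
  exactly to standard PLS1 (verified against scikit-learn in the tests).
- **Outlier screening** — samples with normalized Mahalanobis distance
  H > 3 in factor-score space are removed before regression; samples whose
  cross-validated residual exceeds T = 2.5 cross-validation standard errors
  are removed after it.
- **Validation statistics** — SEC, SECV from seven-group cross-validation,
  RMSEP, R², the C_NIR = a·C_Ref + b regression line, and the paired
  Student *t*-test comparing NIR predictions with the reference chemistry.
- **Assay arithmetic** — standard curves, absorbance→concentration
  conversion, TEAC and the % inhibition formula 100·(A₀ − A₁)/A₀.
- **Synthetic data** — a generator producing propolis-like spectra
  (dominant matrix background, narrow analyte bands, per-replicate
  multiplicative scatter, baseline drift, noise) with known ground truth,
  so every stage is testable without instrument data.

Estimators follow scikit-learn conventions (`fit`/`transform`/`predict`,
trailing-underscore fitted attributes) and compose with sklearn tooling.

## Worked example

Simulate a 99-sample triplicate study, split it 70/29, screen outliers,
calibrate all five constituents with their default treatments and validate
externally:

```python
from nircal import RunConfig, SyntheticConfig, run_study

config = RunConfig(seed=1, outdir="demo")
config.simulate = SyntheticConfig()          # 99 samples, triplicate scans
calibration, validation, models, reports, data = run_study(config)

for c, r in calibration.items():
    print(f"{c:12s} N={r.n_retained:2d} factors={r.n_factors} "
          f"SEC={r.sec:7.2f} SECV={r.secv:7.2f} R2={r.r2:.3f}")
```

```text
quercetin    N=70 factors=2 SEC=   2.12 SECV=   3.80 R2=0.962
rutin        N=70 factors=3 SEC=   2.88 SECV=   3.04 R2=0.996
pinocembrin  N=69 factors=5 SEC=   1.06 SECV=   6.37 R2=0.967
abts         N=70 factors=2 SEC= 248.90 SECV= 254.36 R2=0.978
inhibition   N=70 factors=5 SEC=   1.62 SECV=   2.91 R2=0.957
```

`N` is the calibration-set size after H/T screening (one pinocembrin sample
was flagged by the T criterion here), `SEC` the standard error of
calibration, `SECV` the seven-group cross-validation error in the
constituent's own units (mg/g, nmol Trolox/mg, % inhibition), and `R²` the
squared correlation of cross-validated predictions with the reference
values. SECV exceeds SEC for every constituent, as it should on noisy data.
External validation on the 29 held-out samples:

```python
for c, v in validation.items():
    print(f"{c:12s} p={v.p_value:.2f} residual mean={v.residual_mean:7.2f} "
          f"RMSEP={v.rmsep:7.2f} R2={v.r2:.3f}")
```

```text
quercetin    p=0.61 residual mean=   0.43 RMSEP=   4.44 R2=0.952
rutin        p=0.79 residual mean=   0.19 RMSEP=   3.79 R2=0.996
pinocembrin  p=0.51 residual mean=   0.93 RMSEP=   7.41 R2=0.938
abts         p=0.80 residual mean= -12.96 RMSEP= 267.18 R2=0.979
inhibition   p=0.28 residual mean=  -0.46 RMSEP=   2.29 R2=0.977
```

Every paired-*t* p-value is above 0.05: the NIR predictions are
statistically indistinguishable from the reference chemistry. Asking the
quercetin model for its five most influential wavelengths returns
1689, 1693, 1687, 1417 and 1923 nm — inside the simulated flavone bands at
1690, 1414 and 1928 nm, confirming the calibration reads the intended
chemistry rather than the baseline.

The same workflow is available from a shell:

```bash
nircal simulate  --seed 1 --outdir sim
nircal calibrate --seed 1 --outdir results
nircal validate  --models results/models \
                 --spectra results/validation_spectra.csv \
                 --reference results/validation_reference.csv
nircal report    --results results
```

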