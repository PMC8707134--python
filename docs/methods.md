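# Methods

`fieldspec` analyses leaf reflectance spectra from replicated plot trials in
which the residual variation is spatially autocorrelated. This note records
the statistical model, the default settings and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## The analysis model

Measurements are spot-level reflectance spectra (350–2500 nm at 1 nm,
2151 bands) from a two-way split-plot trial: a main-plot factor applied to
block halves (e.g. a soil amendment, levels NO/YES) and a sub-plot factor
applied to plots within halves (e.g. five crop treatments). The pipeline is:

1. **Preprocessing.** Detector-junction steps at 1000 and 1800 nm are removed
   by additive segment offsetting (each longer-wavelength segment shifted so
   its first point matches the linear extrapolation of the two preceding grid
   points), then the spectrum is averaged into 215 ten-nm bins; the trailing
   2500 nm point is folded into the last bin so the count is exact.
   Multiplicative scatter correction and Savitzky–Golay smoothing (window 11,
   order 2, truncated-window edge handling) are implemented but off by
   default: correlation PCA of contact-probe reflectance usually explains
   more variance on minimally treated spectra, so the default chain is
   splice + binning only.
2. **Correlation PCA.** Eigen-decomposition of the 215-band correlation
   matrix; components with eigenvalue strictly greater than 1 are candidates
   (Kaiser), and the smallest prefix of candidates whose cumulative explained
   variance exceeds 0.97 is retained (all candidates, with a warning, if none
   does). Retained loadings are VARIMAX-rotated (Kaiser row normalization,
   classical pairwise rotations with the closed-form optimal angle, tolerance
   1e-8). Scores are least-squares factor scores `Z L (L'L)^{-1}` from the
   standardized data, centred to mean exactly 0 — score standard deviations
   are therefore below 1, intentionally; no rescaling is applied. Each
   component's sign is fixed so its largest-magnitude loading is positive.
   Salient wavelengths are the maximal runs where |loading × 100| ≥ 80.
3. **Diagnostics.** Normality of each score vector is tested with three
   composite-null EDF tests (Lilliefors KS, Cramér–von Mises with Stephens'
   modification, Anderson–Darling). When at least two of the three reject at
   α = 0.05 the component is replaced by Blom rank-normal scores
   Φ⁻¹((r − 3/8)/(n + ¼)) with average ranks for ties; requiring two of three
   reproduces the intended branch behaviour (a heavily skewed component fails
   all three tests; near-normal ones fail none) while being robust to a
   single marginal test. Variance homogeneity per factor uses classical
   Levene (deviations from group means). Global spatial autocorrelation of
   the OLS residuals uses Moran's I and Geary's c with moments under the
   normality null and two-sided Z tests. The weight matrix is binary with a
   1.0 m cutoff (two within-plot neighbour rings) and is not row-standardized;
   the construction is configurable because printed autocorrelation tables
   rarely state it.
4. **Variogram stage.** The empirical semivariogram of the OLS residuals uses
   0.5 m lags (the spot spacing) up to half the maximum pairwise distance.
   Spherical-with-nugget and pure-nugget models are fitted by weighted least
   squares (pair-count weights, bounded trust-region least squares,
   deterministic multistart over five range initializations) with
   Gauss–Newton standard errors. The spherical model is selected when its
   partial sill is significant at 0.05 and the range is interior; otherwise
   pure nugget.
5. **Spatial mixed model.** z = Mβ + ε with indicator fixed effects
   (intercept, main, sub, interaction; reference-level constraint on the last
   level of each factor) and residual covariance from the selected variogram:
   c(h) = σ₀ + σ − γ(h) for h > 0, c(0) = σ₀ + σ (nugget at zero separation
   only). Variance parameters are estimated by REML (L-BFGS-B on
   log-variances and a logistic transform of the range; LSE fit as the
   initialization plus two scaled perturbations as extra starts), fixed
   effects by GLS at the optimum. When Levene's test on the main factor is
   significant and each group supports a variogram fit, separate residual
   models are fitted per main level with zero cross-group covariance (block
   diagonal) while β stays jointly estimated; grouping by the five-level
   sub factor is refused — 8 plots per group cannot support five separate
   variogram fits. Wald F tests use marginal (LS-mean) contrasts with
   denominator df = n − rank; pairwise LS-mean differences use the same df.
   An OLS fit with the identical inference machinery is reported for
   comparison.

## Synthetic data generator

Because no field spectra are distributed with the package, every stage is
validated on synthetic trials with known truth:

* **Design:** 4 blocks (beds 1.3 m deep, 0.5 m alleys), each split into two
  halves 2 m apart (the two-tunnel layout), 5 plots of 3.0 × 1.3 m per half,
  12 spots per plot on a centred 6 × 2 grid at 0.5 m spacing (the widest grid
  that fits the rectangle). Randomization of main levels to halves and sub
  levels to plots is seeded; geometry is deterministic.
* **Responses:** per-spot value = grand mean + sum-to-zero main/sub/
  interaction adjustments + a zero-mean Gaussian field drawn exactly via
  Cholesky factorization of the variogram covariance. Default parameter
  scales mirror those reported for real trials of this kind: nuggets
  0.26–0.92, partial sills 0.02–0.11, ranges 2.8–11.2 m, treatment
  differences 0.2–0.6 (the chemical-standard minus untreated-control
  difference is set to 0.376 on the water-related component). One component
  carries main-level heteroscedasticity (pure nugget for NO, short-range
  spherical for YES).
* **Spectra:** base green-leaf curve + three latent score fields times smooth
  loading shapes — a SWIR water/biochemistry envelope (peaks 1450/1885/1940
  nm), the NIR structural plateau (715–1375 nm), and a VIS pigment envelope
  (peaks 495/650 nm) — plus wavelength-smooth instrument noise (sd 0.001,
  15 nm correlation scale) and per-row additive detector steps at 1000/1800
  nm (sd 0.004) that the splice correction must remove. The three envelopes
  jointly cover the grid so that, as in measured leaf spectra, almost every
  band is dominated by one latent factor; amplitudes (0.030/0.027/0.024) were
  set so correlation PCA retains exactly three components with top-3
  cumulative variance ≈ 0.99.

What the generator does **not** emulate: radiative transfer or any leaf
biophysics, nonlinear band interactions, anisotropy, drift/trend in the
field, measurement outliers, or non-Gaussian residuals (except the optional
exponentiated latent used to exercise the rank-normal branch). Passing tests
therefore show that the pipeline recovers the *statistical* structure it
models, not that the model is adequate for any particular crop.

## Numerical choices and known limitations

* **Binning** is exact integer arithmetic (215 bins; last bin has 11
  members); the mean of the full bins preserves the grand mean exactly.
* **Savitzky–Golay edges** are handled by refitting the polynomial on the
  truncated asymmetric window (no padding), so exact polynomials of the
  filter order are reproduced at the edges too.
* **Variogram LSE inference is anti-conservative.** Gauss–Newton t tests
  treat the lag estimates as independent, but lags built from overlapping
  pairs are strongly correlated: under iid data the reported partial-sill SE
  understates the sampling spread several-fold and the model selection picks
  a spurious spherical component in roughly a third of null datasets. This
  matches the inference style customarily reported with such tables (whose
  t values are implausibly large for the same reason). The REML stage is
  initialized by, but not bound to, the LSE fit, and re-decides the effective
  structure; treat Table-5-style t values as descriptive.
* **REML** uses exact dense Cholesky factorizations (no approximation); the
  single-group iid case short-circuits to the closed form σ₀ = RSS/(n−rank).
  Non-convergence after all starts is flagged on the fit object. Standard
  errors of variance parameters come from a central-difference observed
  information matrix on the raw (σ₀, σ, ρ) scale, with one-sided normal
  p-values as is conventional for bounded variance components.
* **Wald F tests are mildly liberal in small samples.** With the plug-in
  REML covariance and residual denominator df, simulation at the package's
  default scales shows per-effect type-I error of 4–10% at nominal 5%
  (largest for effects randomized at the scale of the spatial range);
  pooled over the three effect tests the rate is ≈ 7%. A Kenward–Roger or
  Satterthwaite correction would repair this but is deliberately out of
  scope; the OLS comparison under the same structured data rejects at 15–35%,
  which is the package's central demonstration of why the spatial model is
  needed.
* **Simulation sizes.** Calibration studies use 20 seeds (PCA retention),
  100 seeds (variogram and grouped-REML recovery on the 480-spot default
  design) and 500 seeds on a reduced 4-block × 6-spot design (n = 240) for
  the type-I study; single-start REML (LSE initialization) is used inside
  the large seed loops.
* The model contains **no whole-plot random error term**: all non-fixed
  variation is carried by the spatially correlated residual. A textbook
  split-plot analysis would add a random main-plot effect; with spatial
  residual correlation the two parameterizations overlap, and the package
  follows the spatial-residual-only formulation.
* Kriging prediction, anisotropic or non-spherical covariance families, and
  oblique factor rotations are out of scope.
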