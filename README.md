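# fieldspec

Spatially-aware mixed-model analysis of hyperspectral reflectance from
replicated field trials.

## The problem

Agronomic plot trials — for example, testing disease-resistance inducers on a
baby-leaf crop under protected cultivation — increasingly use proximal
hyperspectral sensing as the response: a spectroradiometer records leaf
reflectance over 350–2500 nm at hundreds of spots across the trial. Classical
ANOVA of such data assumes independent residuals, but measurements made
centimetres to metres apart on a crop bed are spatially autocorrelated.
Ignoring that correlation overstates the evidence for treatment effects and
inflates the type-I error. `fieldspec` implements the full pipeline that
deals with this, for statisticians and agronomists who analyse plot trials
from Python:

1. **Preprocessing** — detector-splice correction, 10-nm binning (2151 → 215
   bands), optional multiplicative scatter correction and Savitzky–Golay
   smoothing;
2. **Correlation PCA** — Kaiser retention plus a 97% cumulative-variance
   rule, VARIMAX rotation, factor scores, salient-band selection at
   |loading × 100| ≥ 80;
3. **Diagnostics** — Kolmogorov–Smirnov (Lilliefors), Cramér–von Mises and
   Anderson–Darling normality tests; Blom rank-normal scores
   y<sub>i</sub> = Φ⁻¹((r<sub>i</sub> − 3/8)/(n + ¼)) for non-normal
   components; Levene's test; Moran's I and Geary's c on OLS residuals;
4. **Geostatistics** — empirical semivariograms and weighted least-squares
   fits of spherical-with-nugget / pure-nugget models;
5. **Spatial linear mixed model** — z = **M**β + ε with
   Cov[e<sub>i</sub>, e<sub>j</sub>] = c(h) = σ₀ + σ − γ(h), where γ is the
   spherical semivariogram with nugget σ₀, partial sill σ and range ρ;
   REML estimation of the covariance parameters (optionally separate models
   per main-plot level under heteroscedasticity), GLS fixed effects, Wald F
   tests, pairwise LS-mean contrasts, and the iid OLS fit for comparison.

Because trials of this kind rarely ship raw spectra, the package includes a
first-class synthetic-trial generator (split-plot geometry, Gaussian random
fields with known variograms, latent-factor spectra) so that every stage is
testable against known ground truth.

## Worked example

```python
from fieldspec.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(synthetic_seed=4, synthetic_skew_component=1,
                        output_dir="report")
result = run_pipeline(config)
for line in result.log:
    print(line)
```

prints (abridged):

```
input: 480 rows x 2151 bands
preprocess: 215 bands after splice+binning
pca: retained 3 PCs, cumulative variance 0.9938
PC1: raw scores kept (0/3 normality tests reject)
PC1: Levene[main] F=10.381 p=0.0014
PC1: morans_i observed=0.0676 expected=-0.0021 Z=2.82 p=0.0048
PC1: variogram selected family=spherical
PC1: grouped REML by main (Levene p=0.0014); families={'YES': 'spherical', 'NO': 'nugget'}
rPC2: rank-normal branch (3/3 normality tests reject at alpha=0.05)
...
```

Reading this: the binned spectra yield three retained components (99.4% of
the variance) aligned with the SWIR-water, NIR-structure and VIS-pigment
latents of the generator. The first component is heteroscedastic across the
compost factor (Levene p = 0.0014), its OLS residuals are spatially
autocorrelated (Moran Z = 2.8),
so the mixed model fits separate residual variograms per compost level; the
second component is heavily skewed, fails all three normality tests, and is
rank-normalized before modelling. `report/` then contains eight CSV tables
(basic statistics, normality, Levene, autocorrelation, variogram LSE, REML
variance parameters + F tests, significant contrasts, OLS comparison), the
full contrast table, a run log of every branch decision, and a summary.

The same run from the shell:

```bash
fieldspec run --synthetic-seed 4 --out report
fieldspec simulate --seed 1 --out trial_spectra.csv   # spectra CSV only
```

The `examples/` directory holds one short script per capability (trial
simulation, preprocessing, PCA, spatial diagnostics, variogram + mixed
model, full pipeline); each prints the numbers it computes and a line on
what they mean.

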