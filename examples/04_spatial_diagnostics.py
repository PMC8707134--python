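"""Distributional and spatial diagnostics on one component's OLS residuals."""

from fieldspec.diagnostics import (
    blom_transform,
    build_weight_matrix,
    gearys_c,
    levene_test,
    morans_i,
    normality_tests,
)
from fieldspec.lmm import build_fixed_design, ols_fit
from fieldspec.simulate import simulate_trial

design, responses, _ = simulate_trial(seed=4)
z = responses["latent0"].to_numpy()  # the SWIR/water-like component

print("normality tests (composite normal null):")
for name, (stat, p) in normality_tests(z).items():
    print(f"  {name}: statistic={stat:.3f}, p={p:.4f}")

scores = blom_transform(z)
print(f"Blom scores: mean={scores.y.mean():.4f}, sd={scores.y.std():.3f}")

f, df1, df2, p = levene_test(z, responses["main"].to_numpy())
print(f"Levene (compost): F={f:.2f} on ({df1}, {df2}) df, p={p:.4f}")

fd = build_fixed_design(design.spots)
resid = ols_fit(z, fd).residuals
w = build_weight_matrix(design.locations, method="binary-cutoff", cutoff=1.0)
for res in (morans_i(resid, w), gearys_c(resid, w)):
    print(f"{res.name}: observed={res.statistic:.3f}, expected={res.expected:.3f}, "
          f"Z={res.z:.2f}, p={res.p_value:.4f}")
# positive Moran Z / negative Geary Z flag spatially structured residuals,
# which the OLS model ignores and the spatial mixed model absorbs
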