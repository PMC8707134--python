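"""Fixed design construction, REML/GLS estimation, F tests and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fieldspec.lmm import (
    build_fixed_design,
    fixed_effect_f_tests,
    lsmean_differences,
    ols_fit,
    reml_fit,
    variance_parameter_table,
)
from fieldspec.simulate import compose_response, default_effect_spec
from fieldspec.variogram import VariogramModel


@pytest.fixture(scope="module")
def fd(default_design):
    return build_fixed_design(default_design.spots)


def test_design_matrix_shapes_and_balance(fd):
    assert fd.full.shape == (480, 18)
    assert fd.X.shape == (480, 10)
    assert set(np.unique(fd.full)) == {0.0, 1.0}
    assert np.all(fd.full[:, 0] == 1)
    # balanced column sums: 240 per main level, 96 per sub level
    main_cols = fd.full[:, 1:3].sum(axis=0)
    sub_cols = fd.full[:, 3:8].sum(axis=0)
    assert np.all(main_cols == 240) and np.all(sub_cols == 96)


def test_design_rejects_unseen_levels(default_design):
    with pytest.raises(ValueError, match="not in declared levels"):
        build_fixed_design(default_design.spots, sub_levels=("TRI", "LAM"))


def test_intercept_only_degenerate_design():
    meta = pd.DataFrame({"main": ["A"] * 12, "sub": ["X"] * 12})
    fd1 = build_fixed_design(meta)
    assert fd1.X.shape == (12, 1)
    z = np.arange(12.0)
    fit = ols_fit(z, fd1)
    assert fit.beta[0] == pytest.approx(z.mean())
    assert fixed_effect_f_tests(fit).empty


def test_ols_f_matches_classical_anova(fd, default_design, rng):
    """Wald F on marginal contrasts = textbook two-way ANOVA under iid."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    z = rng.standard_normal(480)
    table = fixed_effect_f_tests(ols_fit(z, fd))
    df = default_design.spots.copy()
    df["z"] = z
    anova = sm.stats.anova_lm(smf.ols("z ~ C(main)*C(sub)", data=df).fit(), typ=2)
    got = table["f_value"].to_numpy()
    want = anova["F"].to_numpy()[:3]
    assert np.allclose(got, want, atol=1e-8)
    assert np.allclose(table["p_value"].to_numpy(), anova["PR(>F)"].to_numpy()[:3], atol=1e-10)


def test_nugget_reml_equals_ols_closed_form(fd, default_design, rng):
    z = rng.standard_normal(480) * 0.8 + 0.3
    ols = ols_fit(z, fd)
    reml = reml_fit(z, fd, default_design.locations, families="nugget")
    sigma2_oracle = float(ols.residuals @ ols.residuals) / ols.df_resid
    assert reml.models[None].nugget == pytest.approx(sigma2_oracle, rel=1e-8)
    assert np.allclose(reml.beta, ols.beta, atol=1e-8)
    f_r = fixed_effect_f_tests(reml)["f_value"].to_numpy()
    f_o = fixed_effect_f_tests(ols)["f_value"].to_numpy()
    assert np.allclose(f_r, f_o, rtol=1e-6)


def test_reml_row_permutation_invariance(fd, default_design):
    spots = default_design.spots
    z = compose_response(default_design, default_effect_spec(0), seed=2)["response"].to_numpy()
    locs = default_design.locations
    fit = reml_fit(z, fd, locs, families="spherical", n_starts=1)

    perm = np.random.default_rng(5).permutation(480)
    fd_p = build_fixed_design(spots.iloc[perm], main_levels=fd.main_levels,
                              sub_levels=fd.sub_levels)
    fit_p = reml_fit(z[perm], fd_p, locs[perm], families="spherical", n_starts=1)
    assert np.allclose(fit.beta, fit_p.beta, atol=1e-6)
    assert fit.models[None].nugget == pytest.approx(fit_p.models[None].nugget, abs=1e-6)


def test_reml_loglik_not_below_initialization(fd, default_design):
    z = compose_response(default_design, default_effect_spec(0), seed=9)["response"].to_numpy()
    locs = default_design.locations
    init = VariogramModel("spherical", nugget=0.5, psill=0.01, range_=1.0)
    fit = reml_fit(z, fd, locs, families="spherical", inits=init, n_starts=1)

    from fieldspec.lmm import _group_indices, _neg2_restricted_ll

    idx_map = _group_indices(None, 480)
    neg2_init, *_ = _neg2_restricted_ll({None: init}, z, fd.X, idx_map, {None: locs})
    assert fit.reml_loglik >= -0.5 * neg2_init - 1e-9


def test_grouped_reml_recovers_heteroscedastic_truth(fd, default_design):
    """Median per-group nugget within 30%; YES structured share in [0.1, 0.5]."""
    labels = default_design.spots["main"].to_numpy()
    spec = default_effect_spec(component=0, with_effects=False)
    ests = []
    for seed in range(20):
        z = compose_response(default_design, spec, seed=100 + seed)["response"].to_numpy()
        fit = reml_fit(z, fd, default_design.locations,
                       families={"NO": "nugget", "YES": "spherical"},
                       groups=labels, n_starts=1)
        yes = fit.models["YES"]
        ests.append((fit.models["NO"].nugget, yes.nugget, yes.structured_share))
    med = np.median(ests, axis=0)
    assert med[0] == pytest.approx(0.259, rel=0.30)
    assert med[1] == pytest.approx(0.256, rel=0.30)
    assert 0.1 <= med[2] <= 0.5


def test_contrast_equals_pooled_two_sample_t():
    meta = pd.DataFrame({
        "main": np.repeat(["A", "B"], 30),
        "sub": ["X"] * 60,
    })
    fd2 = build_fixed_design(meta)
    rng = np.random.default_rng(4)
    z = np.concatenate([rng.normal(0.5, 1, 30), rng.normal(0.0, 1, 30)])
    fit = ols_fit(z, fd2)
    table = lsmean_differences(fit, which="main")
    t_stat, p = stats.ttest_ind(z[:30], z[30:])
    row = table.iloc[0]
    assert row.t_value == pytest.approx(t_stat, abs=1e-10)
    assert row.p_value == pytest.approx(p, abs=1e-10)


def test_contrast_antisymmetry(fd, rng):
    z = rng.standard_normal(480)
    fit = ols_fit(z, fd)
    va = fit.fd.lsmean_vector(sub="CHE") - fit.fd.lsmean_vector(sub="CTR")
    est_ab, se_ab, *_ = fit.contrast(va)
    est_ba, se_ba, *_ = fit.contrast(-va)
    assert est_ab == pytest.approx(-est_ba, abs=1e-12)
    assert se_ab == pytest.approx(se_ba, abs=1e-12)


def test_contrast_calibration_under_null(fd, default_design):
    """~5% of pairwise contrasts significant when no effects exist."""
    sig = total = 0
    for seed in range(60):
        z = np.random.default_rng(seed).standard_normal(480)
        fit = ols_fit(z, fd)
        table = lsmean_differences(fit, which="sub")
        sig += int(table.significant.sum())
        total += len(table)
    assert 0.02 <= sig / total <= 0.09


def test_fixed_effect_power_at_study_effect_size(fd, default_design):
    """CHE-CTR difference 0.376 with sigma0 = 0.4: sub-effect power > 50%."""
    spec = default_effect_spec(component=0)
    spec = type(spec)(
        grand_mean=0.0, main_effects={"NO": 0.0, "YES": 0.0},
        sub_effects=spec.sub_effects, interaction_effects=spec.interaction_effects,
        variograms={None: VariogramModel("nugget", nugget=0.4)},
    )
    hits = 0
    n_seeds = 60
    for seed in range(n_seeds):
        z = compose_response(default_design, spec, seed=seed)["response"].to_numpy()
        p = fixed_effect_f_tests(ols_fit(z, fd)).set_index("effect").loc["Sub", "p_value"]
        hits += p < 0.05
    assert hits / n_seeds > 0.5


def test_ols_f_tends_higher_under_structure(fd, default_design):
    """OLS main-effect F >= spatial-model F in most structured simulations."""
    locs = default_design.locations
    model = VariogramModel("spherical", nugget=0.15, psill=0.15, range_=2.77)
    chol = np.linalg.cholesky(model.covariance_matrix(locs))
    higher = 0
    n_seeds = 20
    for seed in range(n_seeds):
        z = chol @ np.random.default_rng(seed).standard_normal(480)
        f_ols = fixed_effect_f_tests(ols_fit(z, fd)).f_value.iloc[0]
        fit = reml_fit(z, fd, locs, families="spherical", n_starts=1)
        f_sp = fixed_effect_f_tests(fit).f_value.iloc[0]
        higher += f_ols >= f_sp
    assert higher / n_seeds > 0.5


def test_variance_parameter_table_layout(fd, default_design):
    z = compose_response(default_design, default_effect_spec(0, with_effects=False),
                         seed=3)["response"].to_numpy()
    fit = reml_fit(z, fd, default_design.locations,
                   families={"NO": "nugget", "YES": "spherical"},
                   groups=default_design.spots["main"].to_numpy(), n_starts=1)
    table = variance_parameter_table(fit)
    assert set(table.columns) == {"group", "parameter", "estimate", "std_error",
                                  "z_value", "p_value"}
    assert len(table) == 4  # NO nugget + YES (psill, range, nugget)
    assert (table.estimate > 0).all()
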