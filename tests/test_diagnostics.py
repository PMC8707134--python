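"""Normality tests, Blom scores, Levene, spatial weights, Moran and Geary."""

import numpy as np
import pytest
from scipy.special import ndtri

from fieldspec.diagnostics import (
    blom_transform,
    build_weight_matrix,
    gearys_c,
    levene_test,
    morans_i,
    normality_tests,
)

# fixed samples whose Cramér–von Mises results were frozen from an
# independent reference implementation of the composite-normal test
CVM_SAMPLE_NORMAL = np.array([
    -1.423825, 1.263728, -0.870662, -0.259173, -0.075343, -0.740885,
    -1.367793, 0.648893, 0.361058, -1.952863, 2.34741, 0.968497,
    -0.759387, 0.902198, -0.466953, -0.06069, 0.788844, -1.256668,
    0.575858, 1.398979,
])
CVM_SAMPLE_SKEWED = np.array([
    0.040503, 0.219685, 0.993272, 0.7426, 0.37209, 0.809778, 0.503546,
    0.334647, 0.313562, 0.349161, 0.162366, 1.698813, 2.371805, 3.19287,
    1.281325, 1.671801, 1.088224, 2.146748, 0.702618, 0.088847, 0.43398,
    2.399746, 1.087537, 3.260049, 0.579917,
])


def test_cvm_against_frozen_reference_values():
    stat, p = normality_tests(CVM_SAMPLE_NORMAL)["cramer_von_mises"]
    assert stat == pytest.approx(0.0293769521, abs=1e-8)
    assert p == pytest.approx(0.8459578022, rel=1e-4)
    stat, p = normality_tests(CVM_SAMPLE_SKEWED)["cramer_von_mises"]
    assert stat == pytest.approx(0.1980242910, abs=1e-8)
    assert p == pytest.approx(0.0050830454, rel=1e-3)


def test_normality_location_scale_invariance(rng):
    x = rng.standard_normal(120)
    a = normality_tests(x)
    b = normality_tests(3.0 + 2.5 * x)
    for key in a:
        assert a[key][0] == pytest.approx(b[key][0], abs=1e-10)


def test_normality_calibration_and_power():
    """~5% rejection under the null; certain rejection at strong skew."""
    reject = {k: 0 for k in ("kolmogorov_smirnov", "cramer_von_mises", "anderson_darling")}
    n_seeds = 200
    for seed in range(n_seeds):
        x = np.random.default_rng(seed).standard_normal(480)
        for key, (_, p) in normality_tests(x).items():
            reject[key] += p < 0.05
    for key, count in reject.items():
        assert 0.02 <= count / n_seeds <= 0.09, key
    # left-skewed sample at the scale seen for the NIR component
    skewed = -np.random.default_rng(1).gamma(2.8, 1.0, size=480)
    assert all(p < 0.01 for _, p in normality_tests(skewed).values())


def test_normality_rejects_constant():
    with pytest.raises(ValueError, match="constant"):
        normality_tests(np.full(50, 1.0))


def test_blom_closed_form_values():
    assert blom_transform(np.array([3.7])).y[0] == pytest.approx(0.0, abs=1e-12)
    y5 = blom_transform(np.array([5.0, 1.0, 3.0, 2.0, 4.0])).y
    assert y5[2] == pytest.approx(0.0, abs=1e-12)            # median
    assert y5[0] == pytest.approx(ndtri(4.625 / 5.25), abs=1e-12)  # maximum
    assert y5[0] == pytest.approx(1.1798, abs=1e-4)


def test_blom_monotone_and_tie_handling():
    x = np.array([2.0, 2.0, 1.0, 5.0, 3.0])
    ns = blom_transform(x)
    assert ns.y[0] == ns.y[1]  # tied values share the average-rank score
    order_in = np.argsort(x, kind="stable")
    assert np.all(np.diff(ns.y[order_in]) >= 0)
    # rank-idempotence: transforming the scores preserves the ordering
    again = blom_transform(ns.y)
    assert np.array_equal(np.argsort(again.y), np.argsort(ns.y))


def test_levene_identical_groups_give_zero():
    x = np.concatenate([np.arange(10.0), np.arange(10.0)])
    g = np.repeat(["a", "b"], 10)
    f, df1, df2, p = levene_test(x, g)
    assert f == pytest.approx(0.0, abs=1e-12)
    assert (df1, df2) == (1, 18)


def test_levene_calibration_and_power():
    null_rej = hetero_rej = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        g = np.repeat(["a", "b"], 240)
        x_null = rng.standard_normal(480)
        x_het = np.concatenate([rng.standard_normal(240), 2.0 * rng.standard_normal(240)])
        null_rej += levene_test(x_null, g)[3] < 0.05
        hetero_rej += levene_test(x_het, g)[3] < 0.05
    assert 0.02 <= null_rej / 200 <= 0.09
    assert hetero_rej / 200 > 0.95


def test_levene_small_group_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        levene_test(np.arange(5.0), np.array(["a", "a", "a", "a", "b"]))


def test_weight_matrix_two_points():
    w = build_weight_matrix(np.array([[0.0, 0.0], [1.0, 0.0]]), cutoff=2.0)
    assert w.s0 == 2.0


def test_weight_matrix_grid_neighbor_counts(default_design):
    """On the 6 x 2 in-plot grid at 0.5 m cutoff, corners have 2 neighbours
    and interior spots 3 (rook adjacency at exactly the grid spacing)."""
    spots = default_design.spots
    one_plot = spots[spots["plot"] == 0][["x", "y"]].to_numpy()
    w = build_weight_matrix(one_plot, cutoff=0.5)
    degrees = np.asarray(w.weights.sum(axis=1)).ravel()
    assert sorted(degrees.tolist()) == [2, 2, 2, 2] + [3] * 8


def test_weight_matrix_isolated_rejected():
    pts = np.array([[0.0, 0.0], [0.4, 0.0], [10.0, 10.0]])
    with pytest.raises(ValueError, match="isolated"):
        build_weight_matrix(pts, cutoff=0.5)


def test_moran_null_expectation_n480(default_design):
    w = build_weight_matrix(default_design.locations, cutoff=1.0)
    x = np.random.default_rng(0).standard_normal(480)
    res = morans_i(x, w)
    assert res.expected == pytest.approx(-1.0 / 479)
    assert round(res.expected, 3) == -0.002


def test_moran_checkerboard_is_minus_one():
    xs, ys = np.meshgrid(np.arange(4), np.arange(4))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    vals = ((xs + ys) % 2 * 2 - 1).ravel().astype(float)
    w = build_weight_matrix(pts, cutoff=1.0)  # rook neighbours
    assert morans_i(vals, w).statistic == pytest.approx(-1.0, abs=1e-12)


def _moran_bruteforce(x, W):
    n = len(x)
    dev = x - x.mean()
    num = sum(W[i, j] * dev[i] * dev[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / (dev @ dev)


def _geary_bruteforce(x, W):
    n = len(x)
    dev = x - x.mean()
    num = sum(W[i, j] * (x[i] - x[j]) ** 2 for i in range(n) for j in range(n))
    return ((n - 1) / (2 * W.sum())) * num / (dev @ dev)


def test_moran_geary_match_bruteforce_oracle(rng):
    pts = rng.uniform(0, 6, size=(40, 2))
    x = rng.standard_normal(40)
    w = build_weight_matrix(pts, method="inverse-distance", cutoff=3.0)
    W = w.weights.toarray()
    assert morans_i(x, w).statistic == pytest.approx(_moran_bruteforce(x, W), abs=1e-12)
    assert gearys_c(x, w).statistic == pytest.approx(_geary_bruteforce(x, W), abs=1e-12)


def test_geary_expectation_and_calibration(default_design):
    w = build_weight_matrix(default_design.locations, cutoff=1.0)
    stats = []
    for seed in range(200):
        x = np.random.default_rng(seed).standard_normal(480)
        res = gearys_c(x, w)
        stats.append(res.statistic)
        assert res.expected == 1.0
    assert 0.97 <= np.mean(stats) <= 1.03


def test_geary_gradient_direction(default_design):
    """A smooth spatial gradient gives c < 1 and negative Z."""
    locs = default_design.locations
    x = locs[:, 0] * 0.1 + locs[:, 1] * 0.05
    w = build_weight_matrix(locs, cutoff=1.0)
    res = gearys_c(x, w)
    assert res.statistic < 1 and res.z < 0
    assert morans_i(x, w).z > 0


def test_structured_fields_detected_directionally(default_design):
    """Spherical-structured fields: Moran Z > 0, Geary Z < 0 in most seeds."""
    from fieldspec.simulate import simulate_spatial_field
    from fieldspec.variogram import VariogramModel

    locs = default_design.locations
    w = build_weight_matrix(locs, cutoff=1.0)
    model = VariogramModel("spherical", nugget=0.256, psill=0.100, range_=2.77)
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        z = simulate_spatial_field(locs, model, seed=seed)
        hits += (morans_i(z, w).z > 0) and (gearys_c(z, w).z < 0)
    assert hits / n_seeds > 0.9
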