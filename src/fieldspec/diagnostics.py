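"""Distributional and spatial-association diagnostics for component scores.

* Normality of each retained component is checked with three EDF tests for
  the composite normal null (mean and variance estimated): Lilliefors'
  Kolmogorov–Smirnov, Cramér–von Mises and Anderson–Darling.  KS and AD are
  delegated to statsmodels; CvM uses Stephens' small-sample modification
  ``W* = W (1 + 0.5/n)`` with the standard piecewise-exponential p-value
  approximation for the estimated-parameter case.
* Heavily non-normal components are replaced by Blom rank-normal scores,
  ``y_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))`` with average ranks for ties.
* Variance homogeneity across factor levels uses classical Levene (one-way
  ANOVA on absolute deviations from group means).
* Global spatial autocorrelation of OLS residuals uses Moran's I and
  Geary's c with moments under the normality null and a two-sided Z test
  (null expectations −1/(n−1) and 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtri
from statsmodels.stats.diagnostic import lilliefors, normal_ad

__all__ = [
    "NormalScores",
    "AutocorrTestResult",
    "WeightSpec",
    "normality_tests",
    "blom_transform",
    "levene_test",
    "build_weight_matrix",
    "morans_i",
    "gearys_c",
]


@dataclass(frozen=True)
class NormalScores:
    """Blom rank-normal scores with the ranks they came from."""

    y: np.ndarray
    ranks: np.ndarray
    n: int


@dataclass(frozen=True)
class AutocorrTestResult:
    """A global autocorrelation statistic with its normality-null inference."""

    name: str
    statistic: float
    expected: float
    std_dev: float

    @property
    def z(self) -> float:
        return (self.statistic - self.expected) / self.std_dev

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


@dataclass(frozen=True)
class WeightSpec:
    """A symmetric, zero-diagonal, non-negative spatial weight matrix."""

    weights: sparse.csr_matrix
    method: str
    cutoff: float

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.weights.sum())


def _cvm_normal(x: np.ndarray):
    """Cramér–von Mises statistic and p for the composite normal null.

    Stephens' modification and p approximation as tabulated for the case of
    both parameters estimated (the same approximation used by common
    implementations, e.g. the `nortest` routines).
    """
    x = np.sort(x)
    n = x.size
    z = stats.norm.cdf((x - x.mean()) / x.std(ddof=1))
    i = np.arange(1, n + 1)
    w2 = 1.0 / (12 * n) + np.sum((z - (2 * i - 1) / (2.0 * n)) ** 2)
    ww = (1.0 + 0.5 / n) * w2
    if ww < 0.0275:
        p = 1 - np.exp(-13.953 + 775.5 * ww - 12542.61 * ww**2)
    elif ww < 0.051:
        p = 1 - np.exp(-5.903 + 179.546 * ww - 1515.29 * ww**2)
    elif ww < 0.092:
        p = np.exp(0.886 - 31.62 * ww + 10.897 * ww**2)
    elif ww < 1.1:
        p = np.exp(1.111 - 34.242 * ww + 12.832 * ww**2)
    else:
        p = 7.37e-10
    return float(w2), float(min(max(p, 0.0), 1.0))


def normality_tests(x: np.ndarray) -> dict:
    """Three composite-normal EDF tests: ``{name: (statistic, p_value)}``."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    ks_stat, ks_p = lilliefors(x, dist="norm", pvalmethod="table")
    ad_stat, ad_p = normal_ad(x)
    cvm_stat, cvm_p = _cvm_normal(x)
    return {
        "kolmogorov_smirnov": (float(ks_stat), float(ks_p)),
        "cramer_von_mises": (cvm_stat, cvm_p),
        "anderson_darling": (float(ad_stat), float(ad_p)),
    }


def blom_transform(x: np.ndarray) -> NormalScores:
    """Blom rank-normal scores; ties get average ranks."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 1:
        raise ValueError("empty input")
    r = stats.rankdata(x, method="average")
    y = ndtri((r - 3.0 / 8.0) / (n + 0.25))
    return NormalScores(y=y, ranks=r, n=n)


def levene_test(x: np.ndarray, groups) -> tuple:
    """Classical Levene's test (deviations from group means).

    Returns ``(F, df1, df2, p)``; every group needs at least two members.
    """
    x = np.asarray(x, dtype=float).ravel()
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [x[groups == g] for g in levels]
    small = [str(g) for g, s in zip(levels, samples) if s.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    f_stat, p = stats.levene(*samples, center="mean")
    return float(f_stat), levels.size - 1, x.size - levels.size, float(p)


def build_weight_matrix(
    locations: np.ndarray, method: str = "binary-cutoff", cutoff: float = 1.0
) -> WeightSpec:
    """Distance-based spatial weights.

    ``binary-cutoff``: w_ij = 1 for 0 < d_ij <= cutoff;
    ``inverse-distance``: w_ij = 1/d_ij for 0 < d_ij <= cutoff.
    Isolated locations (no neighbour within the cutoff) are rejected.
    """
    locations = np.asarray(locations, dtype=float)
    n = locations.shape[0]
    if n < 2:
        raise ValueError("need at least 2 locations")
    d = squareform(pdist(locations))
    mask = (d > 0) & (d <= cutoff)
    if method == "binary-cutoff":
        w = mask.astype(float)
    elif method == "inverse-distance":
        w = np.where(mask, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    else:
        raise ValueError(f"unknown weight method {method!r}")
    isolated = np.flatnonzero(w.sum(axis=1) == 0)
    if isolated.size:
        raise ValueError(f"isolated locations at cutoff {cutoff}: {isolated.tolist()}")
    return WeightSpec(weights=sparse.csr_matrix(w), method=method, cutoff=cutoff)


def _weight_sums(w: sparse.csr_matrix):
    s0 = float(w.sum())
    wt = w + w.T
    s1 = 0.5 * float(wt.multiply(wt).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(np.sum((row + col) ** 2))
    return s0, s1, s2


def morans_i(x: np.ndarray, w: WeightSpec) -> AutocorrTestResult:
    """Moran's I with expectation and variance under the normality null."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("constant input")
    W = w.weights
    s0, s1, s2 = _weight_sums(W)
    num = float(dev @ (W @ dev))
    stat = (n / s0) * num / denom
    expected = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - expected**2
    return AutocorrTestResult("morans_i", float(stat), expected, float(np.sqrt(var)))


def gearys_c(x: np.ndarray, w: WeightSpec) -> AutocorrTestResult:
    """Geary's c with expectation 1 and variance under the normality null."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("constant input")
    W = w.weights.tocoo()
    s0, s1, s2 = _weight_sums(w.weights)
    num = float(np.sum(W.data * (x[W.row] - x[W.col]) ** 2))
    stat = ((n - 1) / (2.0 * s0)) * num / denom
    var = ((2 * s1 + s2) * (n - 1) - 4 * s0**2) / (2 * (n + 1) * s0**2)
    return AutocorrTestResult("gearys_c", float(stat), 1.0, float(np.sqrt(var)))
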