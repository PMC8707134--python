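"""Semivariogram models, empirical variograms and weighted least-squares fits.

The residual covariance of the spatial mixed model is parameterized through an
isotropic variogram.  Two families are supported:

* ``"nugget"`` — pure nugget: spatially uncorrelated variance ``sigma0``;
* ``"spherical"`` — nugget ``sigma0`` plus a spherical structured component
  with partial sill ``sigma`` and range ``rho`` (metres):

  .. math::

      \\gamma(h) = \\sigma_0 + \\sigma\\,[1.5\\,(h/\\rho) - 0.5\\,(h/\\rho)^3]
      \\quad (0 < h < \\rho), \\qquad \\gamma(h) = \\sigma_0 + \\sigma
      \\quad (h \\ge \\rho),

  with :math:`\\gamma(0) = 0`.  The covariance is
  :math:`c(h) = \\sigma_0 + \\sigma - \\gamma(h)` for :math:`h > 0` and
  :math:`c(0) = \\sigma_0 + \\sigma`; the nugget contributes only at exactly
  zero separation (the standard geostatistical convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "evaluate_model",
    "empirical_variogram",
    "fit_variogram_lse",
    "select_model",
]

#: minimum pair count for a lag to be considered well populated
MIN_PAIRS_PER_LAG = 30


@dataclass(frozen=True)
class VariogramModel:
    """An isotropic variogram/covariance model.

    Parameters
    ----------
    family:
        ``"spherical"`` or ``"nugget"``.
    nugget:
        Spatially uncorrelated variance sigma0 (>= 0).
    psill:
        Partial sill sigma (>= 0; 0 for the nugget family).
    range_:
        Range rho in metres (> 0 for the spherical family).
    stderr, tvalues, pvalues:
        Per-parameter inference, filled in by :func:`fit_variogram_lse`.
    """

    family: str
    nugget: float
    psill: float = 0.0
    range_: float | None = None
    stderr: dict = field(default=None, compare=False)
    tvalues: dict = field(default=None, compare=False)
    pvalues: dict = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "nugget"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.family == "spherical":
            if self.range_ is None or self.range_ <= 0:
                raise ValueError("spherical family requires range_ > 0")
        elif self.psill != 0:
            raise ValueError("nugget family has no partial sill")

    @property
    def sill(self) -> float:
        """Total sill sigma0 + sigma."""
        return self.nugget + self.psill

    @property
    def structured_share(self) -> float:
        """Partial sill as a fraction of the total sill."""
        return self.psill / self.sill if self.sill > 0 else 0.0

    def semivariogram(self, h):
        """gamma(h) for distances ``h`` (scalar or array), with gamma(0)=0."""
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("distances must be non-negative")
        gamma = np.full(h.shape, self.sill)
        if self.family == "spherical":
            inside = (h > 0) & (h < self.range_)
            u = h[inside] / self.range_
            gamma[inside] = self.nugget + self.psill * (1.5 * u - 0.5 * u**3)
        gamma[h == 0] = 0.0
        return gamma if gamma.shape else float(gamma)

    def covariance(self, h):
        """c(h): total sill minus gamma(h); equals the sill at h = 0."""
        h = np.asarray(h, dtype=float)
        c = self.sill - np.asarray(self.semivariogram(h))
        return c if c.shape else float(c)

    def covariance_matrix(self, locations: np.ndarray) -> np.ndarray:
        """Dense covariance matrix for a set of (x, y) coordinates."""
        locations = np.asarray(locations, dtype=float)
        n = locations.shape[0]
        if n == 1:
            return np.array([[self.sill]])
        d = squareform(pdist(locations))
        cov = self.covariance(d)
        np.fill_diagonal(cov, self.sill)
        return cov


#: convenience alias matching the "evaluate the model at h" operation
def evaluate_model(model: VariogramModel, h) -> tuple:
    """Return ``(c(h), gamma(h))`` for distances ``h``."""
    return model.covariance(h), model.semivariogram(h)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram estimate.

    ``gamma_hat[k] = (1 / 2 N_k) * sum over pairs in lag k of (z_i - z_j)^2``.
    """

    lag_centers: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray
    lag_width: float
    max_dist: float

    @property
    def well_populated(self) -> np.ndarray:
        """Boolean mask of lags with at least MIN_PAIRS_PER_LAG pairs."""
        return self.pair_counts >= MIN_PAIRS_PER_LAG

    @property
    def usable(self) -> np.ndarray:
        """Mask of lags containing any pairs."""
        return self.pair_counts > 0


def empirical_variogram(
    values: np.ndarray,
    locations: np.ndarray,
    lag_width: float = 0.5,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Estimate the empirical semivariogram of ``values`` at ``locations``.

    ``max_dist`` defaults to half the maximum pairwise distance, a standard
    geostatistical rule of thumb.  Lags with fewer than 30 pairs are kept but
    flagged via :attr:`EmpiricalVariogram.well_populated`.
    """
    values = np.asarray(values, dtype=float).ravel()
    locations = np.asarray(locations, dtype=float)
    if values.shape[0] != locations.shape[0]:
        raise ValueError("values and locations must align")
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")
    if values.shape[0] < 30:
        warnings.warn("fewer than 30 points: variogram estimate is unstable", stacklevel=2)

    d = pdist(locations)
    if max_dist is None:
        max_dist = 0.5 * float(d.max())
    if max_dist < d.min():
        raise ValueError("max_dist is below the smallest pairwise distance")

    sq = pdist(values[:, None], metric="sqeuclidean")
    keep = d <= max_dist
    bins = np.floor(d[keep] / lag_width).astype(int)
    n_lags = int(np.floor(max_dist / lag_width)) + 1
    counts = np.bincount(bins, minlength=n_lags)
    sums = np.bincount(bins, weights=sq[keep], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma_hat = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = (np.arange(n_lags) + 0.5) * lag_width
    return EmpiricalVariogram(
        lag_centers=centers,
        gamma_hat=gamma_hat,
        pair_counts=counts,
        lag_width=lag_width,
        max_dist=float(max_dist),
    )


def _spherical_gamma(theta, h):
    sigma0, sigma, rho = theta
    u = np.minimum(h / rho, 1.0)
    return sigma0 + sigma * (1.5 * u - 0.5 * u**3)


def _attach_inference(model: VariogramModel, names, est, jac, wres, n_lags) -> VariogramModel:
    """Gauss–Newton standard errors and t tests for the fitted parameters."""
    p = len(names)
    dof = n_lags - p
    if dof <= 0:
        return model
    s2 = float(wres @ wres) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return model
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    stderr, tv, pv = {}, {}, {}
    for name, e, s in zip(names, est, se):
        stderr[name] = float(s)
        tv[name] = float(e / s) if s > 0 else np.inf
        pv[name] = float(2.0 * t_dist.sf(abs(tv[name]), dof)) if np.isfinite(tv[name]) else 0.0
    return replace(model, stderr=stderr, tvalues=tv, pvalues=pv)


def fit_variogram_lse(ev: EmpiricalVariogram, family: str = "spherical") -> VariogramModel:
    """Weighted (pair-count) least-squares fit of a variogram model.

    The objective is ``sum_k N_k (gamma_hat_k - gamma(theta; h_k))^2`` over the
    usable lags.  The spherical fit runs a deterministic multistart over five
    range initializations spread across the lag span; approximate standard
    errors come from the Gauss–Newton covariance at the optimum.  If the
    spherical optimization fails on every start, a nugget-family fallback is
    returned with a warning.
    """
    usable = ev.usable
    h = ev.lag_centers[usable]
    g = ev.gamma_hat[usable]
    n_k = ev.pair_counts[usable].astype(float)
    w = np.sqrt(n_k)

    if family == "nugget":
        if h.size < 1:
            raise ValueError("no usable lags")
        sigma0 = float(np.sum(n_k * g) / np.sum(n_k))
        model = VariogramModel("nugget", nugget=sigma0)
        jac = w[:, None]  # d(resid)/d(sigma0) with weights
        wres = w * (g - sigma0)
        return _attach_inference(model, ["nugget"], [sigma0], jac, wres, h.size)

    if family != "spherical":
        raise ValueError(f"unknown family {family!r}")
    if h.size < 3:
        raise ValueError("spherical fit needs at least 3 usable lags")

    h_max = float(h.max())
    sill0 = float(np.sum(n_k * g) / np.sum(n_k))

    def resid(theta):
        return w * (g - _spherical_gamma(theta, h))

    best = None
    for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
        x0 = np.array([0.7 * sill0, max(0.3 * sill0, 1e-8), frac * h_max])
        try:
            res = least_squares(
                resid,
                x0,
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, h_max]),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        warnings.warn("spherical variogram fit failed; falling back to pure nugget", stacklevel=2)
        return fit_variogram_lse(ev, family="nugget")

    sigma0, sigma, rho = best.x
    model = VariogramModel("spherical", nugget=float(sigma0), psill=float(sigma), range_=float(rho))
    return _attach_inference(
        model, ["nugget", "psill", "range"], best.x, best.jac, best.fun, h.size
    )


def select_model(ev: EmpiricalVariogram, alpha: float = 0.05) -> VariogramModel:
    """Choose between the spherical-with-nugget and pure-nugget families.

    The spherical model is accepted only when its partial sill is significantly
    different from zero (t test at ``alpha``) and the fitted range is interior
    to the lag span; otherwise the pure nugget fit is returned.
    """
    usable = int(ev.usable.sum())
    if usable < 3:
        return fit_variogram_lse(ev, family="nugget")
    sph = fit_variogram_lse(ev, family="spherical")
    if sph.family != "spherical":
        return sph
    h_max = float(ev.lag_centers[ev.usable].max())
    p_sigma = (sph.pvalues or {}).get("psill", 1.0)
    interior = 1e-4 < (sph.range_ or 0.0) < 0.999 * h_max
    if p_sigma < alpha and interior and sph.psill > 0:
        return sph
    return fit_variogram_lse(ev, family="nugget")
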