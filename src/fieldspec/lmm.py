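"""Spatial linear mixed model: z = M beta + eps with variogram residuals.

The fixed part is a two-way treatment structure (main-plot factor, sub-plot
factor, their interaction) encoded as an indicator design; the random part is
a zero-mean Gaussian residual whose covariance follows an isotropic variogram
model, optionally with separate parameters per main-factor level
(heteroscedastic groups, zero cross-group covariance so the joint covariance
is block diagonal while the fixed effects stay jointly estimated).

Variance parameters are estimated by REML (restricted maximum likelihood),
maximizing

.. math::

    -2\\,\\ell_R = \\log|\\Sigma| + \\log|X'\\Sigma^{-1}X|
                  + (z - X\\hat\\beta)'\\Sigma^{-1}(z - X\\hat\\beta)

over the variogram parameters, with :math:`\\hat\\beta` the GLS solution at
each candidate covariance.  Fixed-effect F statistics are Wald tests on
marginal (LS-mean) contrasts with denominator degrees of freedom
``n - rank(X)``; in the iid nugget limit they reduce exactly to classical
two-way ANOVA, which the test-suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist

from fieldspec.variogram import VariogramModel

__all__ = [
    "FixedDesign",
    "LMMFit",
    "build_fixed_design",
    "reml_fit",
    "ols_fit",
    "fixed_effect_f_tests",
    "lsmean_differences",
    "variance_parameter_table",
]


@dataclass(frozen=True)
class FixedDesign:
    """Indicator fixed-effect design for a two-way treatment structure.

    ``full`` is the n x t over-parameterized 0/1 matrix (intercept, one
    column per main level, per sub level, per interaction cell).  ``X`` is
    the reduced full-rank design under the reference-level constraint (the
    last level of each factor, and every interaction cell touching a
    reference level, is constrained to zero).
    """

    full: np.ndarray
    X: np.ndarray
    column_names: list
    main_levels: tuple
    sub_levels: tuple
    main: np.ndarray
    sub: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    def cell_mean_vector(self, main: str, sub: str) -> np.ndarray:
        """Coefficient vector whose inner product with beta is E[z | cell]."""
        if main not in self.main_levels or sub not in self.sub_levels:
            raise ValueError(f"unknown cell ({main}, {sub})")
        v = np.zeros(self.rank)
        names = self.column_names
        v[0] = 1.0
        for token, flag in ((f"main[{main}]", True), (f"sub[{sub}]", True),
                            (f"int[{main}:{sub}]", True)):
            if token in names and flag:
                v[names.index(token)] = 1.0
        return v

    def lsmean_vector(self, main: str | None = None, sub: str | None = None) -> np.ndarray:
        """LS-mean coefficient vector: average of cell means over the
        levels of any factor not pinned."""
        mains = [main] if main is not None else list(self.main_levels)
        subs = [sub] if sub is not None else list(self.sub_levels)
        vs = [self.cell_mean_vector(m, s) for m in mains for s in subs]
        return np.mean(vs, axis=0)


def build_fixed_design(meta: pd.DataFrame, main_levels=None, sub_levels=None) -> FixedDesign:
    """Build the indicator design from per-row ``main``/``sub`` labels.

    Level order defaults to order of first appearance; the last level of each
    factor is the reference level.  Unseen labels in the data are rejected.
    """
    main = meta["main"].to_numpy()
    sub = meta["sub"].to_numpy()
    if main_levels is None:
        main_levels = tuple(pd.unique(main))
    if sub_levels is None:
        sub_levels = tuple(pd.unique(sub))
    unseen = (set(main) - set(main_levels)) | (set(sub) - set(sub_levels))
    if unseen:
        raise ValueError(f"labels not in declared levels: {sorted(unseen)}")

    n = len(main)
    full_cols, full_names = [np.ones(n)], ["intercept"]
    for m in main_levels:
        full_cols.append((main == m).astype(float))
        full_names.append(f"main[{m}]")
    for s in sub_levels:
        full_cols.append((sub == s).astype(float))
        full_names.append(f"sub[{s}]")
    for m in main_levels:
        for s in sub_levels:
            full_cols.append(((main == m) & (sub == s)).astype(float))
            full_names.append(f"int[{m}:{s}]")
    full = np.column_stack(full_cols)

    red_cols, red_names = [np.ones(n)], ["intercept"]
    for m in main_levels[:-1]:
        red_cols.append((main == m).astype(float))
        red_names.append(f"main[{m}]")
    for s in sub_levels[:-1]:
        red_cols.append((sub == s).astype(float))
        red_names.append(f"sub[{s}]")
    for m in main_levels[:-1]:
        for s in sub_levels[:-1]:
            red_cols.append(((main == m) & (sub == s)).astype(float))
            red_names.append(f"int[{m}:{s}]")
    X = np.column_stack(red_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("reduced design is rank deficient (empty cells?)")
    return FixedDesign(
        full=full, X=X, column_names=red_names,
        main_levels=tuple(main_levels), sub_levels=tuple(sub_levels),
        main=main, sub=sub,
    )


@dataclass(frozen=True)
class LMMFit:
    """A fitted (REML or OLS) linear model with its covariance machinery."""

    fd: FixedDesign
    beta: np.ndarray
    cov_beta: np.ndarray
    models: dict                 # group label (or None) -> VariogramModel
    groups: np.ndarray | None
    reml_loglik: float
    converged: bool
    n_iter: int
    residuals: np.ndarray
    method: str                  # "reml" | "ols"
    var_param_cov: dict = field(default=None, compare=False)

    @property
    def df_resid(self) -> int:
        return self.fd.n - self.fd.rank

    def contrast(self, L: np.ndarray):
        """Estimate, SE, t and two-sided p for a single contrast row."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.beta)
        se = float(np.sqrt(L @ self.cov_beta @ L))
        t = est / se
        p = float(2.0 * stats.t.sf(abs(t), self.df_resid))
        return est, se, t, p


# ---------------------------------------------------------------------------
# REML machinery


def _group_indices(groups, n):
    if groups is None:
        return {None: np.arange(n)}
    groups = np.asarray(groups)
    return {g: np.flatnonzero(groups == g) for g in pd.unique(groups)}


def _unpack(theta, layout):
    """Transform the unconstrained vector into per-group VariogramModels."""
    theta = np.clip(theta, -30.0, 30.0)  # keep exp() finite during line searches
    models = {}
    pos = 0
    for g, family, d_max in layout:
        if family == "nugget":
            models[g] = VariogramModel("nugget", nugget=float(np.exp(theta[pos])))
            pos += 1
        else:
            sigma0 = float(np.exp(theta[pos]))
            sigma = float(np.exp(theta[pos + 1]))
            rho = 1e-3 + (d_max - 1e-3) / (1.0 + np.exp(-theta[pos + 2]))
            models[g] = VariogramModel("spherical", nugget=sigma0, psill=sigma, range_=float(rho))
            pos += 3
    return models


def _pack(models, layout):
    theta = []
    for g, family, d_max in layout:
        m = models[g]
        if family == "nugget":
            theta.append(np.log(max(m.nugget, 1e-8)))
        else:
            rho = np.clip(m.range_ if m.range_ else 0.3 * d_max, 1.01e-3, 0.999 * d_max)
            frac = (rho - 1e-3) / (d_max - 1e-3)
            theta.extend([
                np.log(max(m.nugget, 1e-8)),
                np.log(max(m.psill, 1e-8)),
                np.log(frac / (1 - frac)),
            ])
    return np.array(theta)


def _neg2_restricted_ll(models, z, X, idx_map, locs_map):
    logdet = 0.0
    xtsix = np.zeros((X.shape[1], X.shape[1]))
    xtsiz = np.zeros(X.shape[1])
    ztsiz = 0.0
    for g, idx in idx_map.items():
        cov = models[g].covariance_matrix(locs_map[g])
        if not np.all(np.isfinite(cov)):
            return None
        try:
            c, low = cho_factor(cov, lower=True)
        except (np.linalg.LinAlgError, ValueError):
            return None
        logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
        xg, zg = X[idx], z[idx]
        six = cho_solve((c, low), xg)
        siz = cho_solve((c, low), zg)
        xtsix += xg.T @ six
        xtsiz += xg.T @ siz
        ztsiz += float(zg @ siz)
    sign, logdet_x = np.linalg.slogdet(xtsix)
    if sign <= 0:
        return None
    beta = np.linalg.solve(xtsix, xtsiz)
    quad = ztsiz - float(beta @ xtsiz)
    return logdet + logdet_x + quad, beta, xtsix


def reml_fit(
    z: np.ndarray,
    fd: FixedDesign,
    locations: np.ndarray,
    families="spherical",
    inits=None,
    groups=None,
    n_starts: int = 3,
    max_iter: int = 200,
) -> LMMFit:
    """REML estimation of the variogram parameters plus GLS fixed effects.

    Parameters
    ----------
    families:
        ``"nugget"``/``"spherical"`` or a per-group-label dict when
        ``groups`` is given.
    inits:
        Optional :class:`VariogramModel` (or per-group dict) to initialize
        the optimizer — typically the least-squares variogram fit of the OLS
        residuals.  Without it a moment-based default is used.
    groups:
        Optional per-row labels; each group gets its own residual model and
        cross-group covariance is zero.
    n_starts:
        Deterministic multistart count (the init plus scaled perturbations).

    The optimizer is bounded quasi-Newton (L-BFGS-B) on log-variances and a
    logistic transform of the range; convergence is declared by the
    optimizer's relative tolerance (1e-8 scale) within ``max_iter``
    iterations.
    """
    z = np.asarray(z, dtype=float).ravel()
    locations = np.asarray(locations, dtype=float)
    X = fd.X
    n = z.size
    idx_map = _group_indices(groups, n)
    locs_map = {g: locations[idx] for g, idx in idx_map.items()}

    if isinstance(families, str):
        families = {g: families for g in idx_map}
    layout = []
    for g in idx_map:
        d_max = float(pdist(locs_map[g]).max()) if len(idx_map[g]) > 1 else 1.0
        layout.append((g, families[g], d_max))

    var_z = float(np.var(z, ddof=1))
    init_models = {}
    for g, family, d_max in layout:
        default = (
            VariogramModel("nugget", nugget=var_z)
            if family == "nugget"
            else VariogramModel("spherical", nugget=0.7 * var_z, psill=0.3 * var_z,
                                range_=0.3 * d_max)
        )
        if inits is None:
            init_models[g] = default
        elif isinstance(inits, VariogramModel):
            init_models[g] = inits if inits.family == family else default
        else:
            cand = inits.get(g, default)
            init_models[g] = cand if cand.family == family else default

    # single shared nugget: the REML optimum is exact, sigma0 = RSS/(n - rank)
    if len(layout) == 1 and layout[0][1] == "nugget":
        g = layout[0][0]
        beta_ols, *_ = np.linalg.lstsq(X, z, rcond=None)
        rss = float((z - X @ beta_ols) @ (z - X @ beta_ols))
        sigma0 = rss / (X.shape[0] - X.shape[1])
        models = {g: VariogramModel("nugget", nugget=sigma0)}
        neg2, beta, xtsix = _neg2_restricted_ll(models, z, X, idx_map, locs_map)
        return LMMFit(
            fd=fd, beta=beta, cov_beta=np.linalg.inv(xtsix), models=models,
            groups=None if groups is None else np.asarray(groups),
            reml_loglik=-0.5 * neg2, converged=True, n_iter=0,
            residuals=z - X @ beta, method="reml",
            var_param_cov=_variance_param_cov(models, layout, z, X, idx_map, locs_map),
        )

    def objective(theta):
        out = _neg2_restricted_ll(_unpack(theta, layout), z, X, idx_map, locs_map)
        return 1e10 if out is None else out[0]

    theta0 = _pack(init_models, layout)
    starts = [theta0]
    for scale in (0.5, 2.0):
        pert = {
            g: (
                VariogramModel("nugget", nugget=m.nugget * scale)
                if m.family == "nugget"
                else VariogramModel(
                    "spherical",
                    nugget=m.nugget * scale,
                    psill=m.psill / scale,
                    range_=m.range_ * scale,
                )
            )
            for g, m in init_models.items()
        }
        starts.append(_pack(pert, layout))

    best = None
    total_iter = 0
    for theta_start in starts[:n_starts]:
        res = optimize.minimize(
            objective,
            theta_start,
            method="L-BFGS-B",
            options=dict(maxiter=max_iter, ftol=1e-12, gtol=1e-10),
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success or best.fun < 1e10)
    if not converged:
        warnings.warn("REML optimization did not converge", stacklevel=2)

    models = _unpack(best.x, layout)
    neg2, beta, xtsix = _neg2_restricted_ll(models, z, X, idx_map, locs_map)
    cov_beta = np.linalg.inv(xtsix)
    resid = z - X @ beta
    var_cov = _variance_param_cov(models, layout, z, X, idx_map, locs_map)
    return LMMFit(
        fd=fd, beta=beta, cov_beta=cov_beta, models=models,
        groups=None if groups is None else np.asarray(groups),
        reml_loglik=-0.5 * neg2, converged=converged, n_iter=total_iter,
        residuals=resid, method="reml", var_param_cov=var_cov,
    )


def _variance_param_cov(models, layout, z, X, idx_map, locs_map):
    """Finite-difference observed-information covariance of (sigma0, sigma, rho).

    Central differences of -2 restricted log-likelihood on the raw parameter
    scale; the asymptotic covariance is 2 * inv(Hessian).
    """
    names, values = [], []
    for g, family, _ in layout:
        m = models[g]
        if family == "nugget":
            names.append((g, "nugget"))
            values.append(m.nugget)
        else:
            names.extend([(g, "nugget"), (g, "psill"), (g, "range")])
            values.extend([m.nugget, m.psill, m.range_])
    values = np.array(values)
    k = values.size

    def f(v):
        ms, pos = {}, 0
        for g, family, _ in layout:
            if family == "nugget":
                ms[g] = VariogramModel("nugget", nugget=max(v[pos], 1e-10))
                pos += 1
            else:
                ms[g] = VariogramModel(
                    "spherical", nugget=max(v[pos], 1e-10),
                    psill=max(v[pos + 1], 0.0), range_=max(v[pos + 2], 1e-6),
                )
                pos += 3
        out = _neg2_restricted_ll(ms, z, X, idx_map, locs_map)
        return np.inf if out is None else out[0]

    h = np.maximum(1e-4, 1e-3 * np.abs(values))
    hess = np.zeros((k, k))
    f0 = f(values)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                vp = values.copy(); vp[i] += h[i]
                vm = values.copy(); vm[i] -= h[i]
                hess[i, i] = (f(vp) - 2 * f0 + f(vm)) / h[i] ** 2
            else:
                vpm = values.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
                vmp = values.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
                vmm = values.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
                vpp = values.copy(); vpp[i] += h[i]; vpp[j] += h[j]
                hess[i, j] = hess[j, i] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    return {name: float(max(cov[i, i], 0.0)) for i, name in enumerate(names)}


def variance_parameter_table(fit: LMMFit) -> pd.DataFrame:
    """REML variance-parameter estimates with SE, z and one-sided p.

    One-sided p-values (P[Z > z]) are the convention for variance components,
    which are bounded below by zero.
    """
    rows = []
    for g, m in fit.models.items():
        params = [("nugget", m.nugget)]
        if m.family == "spherical":
            params = [("psill", m.psill), ("range", m.range_), ("nugget", m.nugget)]
        for name, est in params:
            var = (fit.var_param_cov or {}).get((g, name))
            se = np.sqrt(var) if var is not None else np.nan
            zval = est / se if se and se > 0 else np.nan
            p = float(stats.norm.sf(zval)) if np.isfinite(zval) else np.nan
            rows.append(dict(group="" if g is None else str(g), parameter=name,
                             estimate=est, std_error=se, z_value=zval, p_value=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OLS comparison fit


def ols_fit(z: np.ndarray, fd: FixedDesign) -> LMMFit:
    """Ordinary least squares with iid residuals (the non-spatial comparison).

    Equivalent to the REML fit under a single shared nugget family: the
    residual variance estimate is RSS / (n - rank).
    """
    z = np.asarray(z, dtype=float).ravel()
    X = fd.X
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    df = fd.n - fd.rank
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    # restricted log-likelihood of the iid model at its REML optimum
    sign, logdet_x = np.linalg.slogdet(X.T @ X / sigma2)
    neg2 = fd.n * np.log(sigma2) + logdet_x + float(resid @ resid) / sigma2
    return LMMFit(
        fd=fd, beta=beta, cov_beta=sigma2 * xtx_inv,
        models={None: VariogramModel("nugget", nugget=sigma2)},
        groups=None, reml_loglik=-0.5 * neg2, converged=True, n_iter=0,
        residuals=resid, method="ols",
    )


# ---------------------------------------------------------------------------
# inference on fixed effects


def _effect_contrasts(fd: FixedDesign, effect: str) -> np.ndarray:
    """Marginal-mean contrast rows spanning one effect's null hypothesis."""
    if effect == "main":
        ref = fd.main_levels[-1]
        return np.array([
            fd.lsmean_vector(main=m) - fd.lsmean_vector(main=ref)
            for m in fd.main_levels[:-1]
        ])
    if effect == "sub":
        ref = fd.sub_levels[-1]
        return np.array([
            fd.lsmean_vector(sub=s) - fd.lsmean_vector(sub=ref)
            for s in fd.sub_levels[:-1]
        ])
    if effect == "interaction":
        mr, sr = fd.main_levels[-1], fd.sub_levels[-1]
        rows = []
        for m in fd.main_levels[:-1]:
            for s in fd.sub_levels[:-1]:
                rows.append(
                    fd.cell_mean_vector(m, s) - fd.cell_mean_vector(m, sr)
                    - fd.cell_mean_vector(mr, s) + fd.cell_mean_vector(mr, sr)
                )
        return np.array(rows)
    raise ValueError(f"unknown effect {effect!r}")


def fixed_effect_f_tests(fit: LMMFit) -> pd.DataFrame:
    """Wald F tests for the main effect, sub effect and interaction.

    ``F = (L b)' (L C L')^{-1} (L b) / q`` with ``C = Cov(beta)``; the
    denominator df is the residual df ``n - rank``.
    """
    fd = fit.fd
    rows = []
    effects = []
    if len(fd.main_levels) > 1:
        effects.append(("main", "Main"))
    if len(fd.sub_levels) > 1:
        effects.append(("sub", "Sub"))
    if len(fd.main_levels) > 1 and len(fd.sub_levels) > 1:
        effects.append(("interaction", "Main x Sub"))
    for key, label in effects:
        L = _effect_contrasts(fd, key)
        q = L.shape[0]
        est = L @ fit.beta
        mid = np.linalg.solve(L @ fit.cov_beta @ L.T, est)
        f_stat = float(est @ mid) / q
        p = float(stats.f.sf(f_stat, q, fit.df_resid))
        rows.append(dict(effect=label, num_df=q, den_df=fit.df_resid,
                         f_value=f_stat, p_value=p))
    return pd.DataFrame(rows)


def lsmean_differences(fit: LMMFit, which: str = "all", alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise LS-mean differences for the requested effect(s).

    ``which`` is one of ``"main"``, ``"sub"``, ``"interaction"`` or ``"all"``.
    Returns the full table with a boolean ``significant`` column at ``alpha``
    (two-sided t with residual df).
    """
    fd = fit.fd
    jobs = []
    if which in ("main", "all"):
        lv = [(m, fd.lsmean_vector(main=m)) for m in fd.main_levels]
        jobs += [("Main", a, b, va - vb) for i, (a, va) in enumerate(lv)
                 for b, vb in lv[i + 1:]]
    if which in ("sub", "all"):
        lv = [(s, fd.lsmean_vector(sub=s)) for s in fd.sub_levels]
        jobs += [("Sub", a, b, va - vb) for i, (a, va) in enumerate(lv)
                 for b, vb in lv[i + 1:]]
    if which in ("interaction", "all"):
        cells = [(f"{m}:{s}", fd.cell_mean_vector(m, s))
                 for m in fd.main_levels for s in fd.sub_levels]
        jobs += [("Main x Sub", a, b, va - vb) for i, (a, va) in enumerate(cells)
                 for b, vb in cells[i + 1:]]
    if not jobs:
        raise ValueError(f"unknown effect selector {which!r}")
    rows = []
    for effect, a, b, L in jobs:
        est, se, t, p = fit.contrast(L)
        rows.append(dict(effect=effect, level_a=a, level_b=b, estimate=est,
                         std_error=se, t_value=t, p_value=p,
                         significant=p < alpha))
    return pd.DataFrame(rows)
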