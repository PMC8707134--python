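"""Correlation-matrix PCA with VARIMAX rotation for binned spectra.

Workflow: eigen-decompose the band correlation matrix; keep the components
with eigenvalue > 1 (Kaiser) and, among those candidates, the smallest prefix
whose cumulative explained-variance proportion exceeds a threshold (default
0.97); VARIMAX-rotate the retained loadings (Kaiser normalization, tolerance
1e-8); compute per-spot scores; and report the salient wavelength intervals
where |loading x 100| clears a threshold (default 80).

Sign convention: each rotated component is flipped, if needed, so that its
largest-magnitude loading is positive — eigen-solvers are sign-ambiguous and
this pins a reproducible orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "correlation_pca",
    "retain_components",
    "varimax_rotate",
    "score_samples",
    "select_salient_bands",
    "spectral_pca",
]


@dataclass(frozen=True)
class PCAResult:
    """Retained, rotated correlation-PCA solution for one spectra matrix."""

    eigenvalues: np.ndarray          # all p eigenvalues, descending
    cumulative_variance: np.ndarray  # cumulative proportion over all PCs
    n_retained: int
    loadings: np.ndarray             # bands x retained, VARIMAX-rotated
    rotation: np.ndarray             # retained x retained orthogonal matrix
    scores: np.ndarray               # rows x retained, mean 0 per column
    wavelengths: np.ndarray
    salient_bands: list              # per PC: list of (start_nm, end_nm)

    @property
    def loadings_x100(self) -> np.ndarray:
        return 100.0 * self.loadings

    def scores_frame(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Score table joined to design metadata, one PC column per component."""
        out = meta.reset_index(drop=True).copy()
        for k in range(self.n_retained):
            out[f"PC{k + 1}"] = self.scores[:, k]
        return out


def correlation_pca(x: np.ndarray):
    """Eigen-decomposition of the correlation matrix of ``x`` (rows = samples).

    Returns ``(eigenvalues, loadings, scores)`` with eigenvalues descending,
    loadings = eigenvector * sqrt(eigenvalue) (band-PC correlations) and
    scores computed from the standardized data (score variance = eigenvalue).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance columns: {dead.tolist()}")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)
    scores = z @ eigvec
    return eigval, loadings, scores


def retain_components(eigenvalues: np.ndarray, cum_threshold: float = 0.97) -> int:
    """Kaiser candidates (eigenvalue > 1) pruned by cumulative variance.

    Among the candidates, the smallest prefix whose cumulative proportion of
    total variance exceeds ``cum_threshold`` is retained; if no prefix
    reaches it, all candidates are kept (with a warning).
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be in descending order")
    n_candidates = int(np.sum(ev > 1.0))
    if n_candidates == 0:
        return 0
    cum = np.cumsum(ev) / ev.sum()
    for k in range(1, n_candidates + 1):
        if cum[k - 1] > cum_threshold:
            return k
    warnings.warn(
        f"cumulative variance of all {n_candidates} Kaiser candidates stays "
        f"below {cum_threshold}; retaining all of them",
        stacklevel=2,
    )
    return n_candidates


def varimax_rotate(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """Orthogonal VARIMAX rotation with Kaiser (row) normalization.

    Maximizes the variance of squared loadings per factor by the classical
    pairwise (Jacobi-style) sweeps, each pair rotated by its closed-form
    optimal angle, until no rotation exceeds ``tol``.  Returns ``(rotated,
    rotation)``; a single-column input is returned unchanged with the
    identity rotation.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    h = np.where(h == 0, 1.0, h)
    B = L / h[:, None]
    R = np.eye(k)
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = B[:, i], B[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (p * (u @ v) - u.sum() * v.sum())
                den = p * (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2)
                angle = 0.25 * np.arctan2(num, den)
                if abs(angle) <= tol:
                    continue
                max_angle = max(max_angle, abs(angle))
                c, s = np.cos(angle), np.sin(angle)
                G = np.array([[c, -s], [s, c]])
                B[:, [i, j]] = B[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        if max_angle <= tol:
            break
    rotated = B * h[:, None]
    # reproducible orientation: largest-|loading| entry positive per column
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs = np.where(signs == 0, 1.0, signs)
    rotated *= signs
    R = R * signs
    # order components by explained variance (sum of squared loadings)
    order = np.argsort(-(rotated**2).sum(axis=0), kind="stable")
    return rotated[:, order], R[:, order]


def score_samples(x: np.ndarray, rotated_loadings: np.ndarray) -> np.ndarray:
    """Least-squares factor scores from standardized data and rotated loadings.

    ``scores = Z L (L'L)^{-1}``, then each column is centred to mean exactly
    zero.  A singular loading cross-product is rejected.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(rotated_loadings, dtype=float)
    if x.shape[1] != L.shape[0]:
        raise ValueError("band dimensions of data and loadings disagree")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    gram = L.T @ L
    if np.linalg.cond(gram) > 1e12:
        raise ValueError("singular loading cross-product")
    scores = z @ L @ np.linalg.inv(gram)
    return scores - scores.mean(axis=0)


def select_salient_bands(
    loadings_x100: np.ndarray, wavelengths: np.ndarray, threshold: float = 80.0
) -> list:
    """Maximal contiguous wavelength runs with |loading x 100| >= threshold.

    Returns one list of ``(start_nm, end_nm)`` intervals per component; a
    component may legitimately have none.
    """
    L = np.atleast_2d(np.asarray(loadings_x100, dtype=float).T).T
    w = np.asarray(wavelengths, dtype=float)
    intervals = []
    for k in range(L.shape[1]):
        mask = np.abs(L[:, k]) >= threshold
        runs = []
        start = None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                runs.append((float(w[start]), float(w[i - 1])))
                start = None
        if start is not None:
            runs.append((float(w[start]), float(w[len(mask) - 1])))
        intervals.append(runs)
    return intervals


def spectral_pca(
    x: np.ndarray,
    wavelengths: np.ndarray,
    cum_threshold: float = 0.97,
    loading_threshold: float = 80.0,
) -> PCAResult:
    """Full PCA stage: decompose, retain, rotate, score, select salient bands."""
    eigval, raw_loadings, _ = correlation_pca(x)
    n_ret = retain_components(eigval, cum_threshold)
    if n_ret == 0:
        raise ValueError("no component passes the Kaiser criterion")
    rotated, rotation = varimax_rotate(raw_loadings[:, :n_ret])
    scores = score_samples(x, rotated)
    salient = select_salient_bands(100.0 * rotated, wavelengths, loading_threshold)
    return PCAResult(
        eigenvalues=eigval,
        cumulative_variance=np.cumsum(eigval) / eigval.sum(),
        n_retained=n_ret,
        loadings=rotated,
        rotation=rotation,
        scores=scores,
        wavelengths=np.asarray(wavelengths, dtype=float),
        salient_bands=salient,
    )
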