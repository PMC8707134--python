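"""Spectral preprocessing: CSV I/O, splice correction, binning, MSC, smoothing.

The processing chain mirrors standard field-spectroradiometry practice:

* **splice correction** — portable VIS-NIR/SWIR instruments use three
  detectors with junctions near 1000 and 1800 nm; each longer-wavelength
  segment is shifted additively so its first point matches the linear
  extrapolation of the preceding segment, removing the step artefact without
  altering segment shapes;
* **10-nm binning** — the 2151-band 1-nm grid (350–2500 nm) is averaged into
  exactly 215 bins, smoothing the spectra and limiting over-fitting risk;
* **MSC** (multiplicative scatter correction) — per-row regression on a
  reference spectrum removes additive and multiplicative scatter components;
* **Savitzky–Golay** — moving least-squares polynomial smoothing.

The default pipeline applies splice correction and binning only; MSC and
Savitzky–Golay are available but off by default, since component analysis of
contact-probe reflectance typically works best on minimally treated spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

__all__ = [
    "SpectrumSet",
    "PreprocessConfig",
    "read_spectra_csv",
    "write_spectra_csv",
    "splice_correct",
    "bin_to_10nm",
    "msc_correct",
    "savitzky_golay",
    "preprocess",
]

META_COLUMNS = ["spot", "plot", "block", "main", "sub", "x", "y"]


@dataclass(frozen=True)
class SpectrumSet:
    """Reflectance rows on a common wavelength grid with per-row metadata.

    ``wavelengths`` must be strictly increasing and match the matrix width;
    ``meta`` carries the design columns (plot, block, main, sub, x, y) in row
    order.  Values outside [0, 1] are legal but draw a warning.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 2:
            raise ValueError("reflectance must be a 2-D matrix")
        if w.ndim != 1 or w.size != r.shape[1]:
            raise ValueError("wavelength count must match matrix width")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance contains non-finite values")
        if len(self.meta) != r.shape[0]:
            raise ValueError("metadata row count must match reflectance rows")
        if np.any(r < 0) or np.any(r > 1):
            warnings.warn("reflectance values outside [0, 1]", stacklevel=2)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)

    @property
    def n_rows(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def with_data(self, wavelengths=None, reflectance=None) -> "SpectrumSet":
        return SpectrumSet(
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            reflectance=self.reflectance if reflectance is None else reflectance,
            meta=self.meta,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing switches and parameters.

    ``sg_window`` is the full Savitzky–Golay window w = 2n + 1 (default 11,
    half-width n = 5) and must exceed ``sg_order``.
    """

    splice_boundaries: tuple = (1000.0, 1800.0)
    bin_width: float = 10.0
    sg_window: int = 11
    sg_order: int = 2
    apply_msc: bool = False
    apply_sg: bool = False

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")


# ---------------------------------------------------------------------------
# CSV dialect: metadata columns then numeric wavelength labels


def read_spectra_csv(path) -> SpectrumSet:
    """Read the wide spectra CSV (metadata columns, then wavelength columns)."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing metadata columns: {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column label: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength header is not strictly increasing")
    refl = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(refl)):
        bad = np.argwhere(~np.isfinite(refl))
        raise ValueError(f"non-finite reflectance at (row, band) {bad[:5].tolist()}")
    return SpectrumSet(wavelengths=wavelengths, reflectance=refl, meta=df[META_COLUMNS].copy())


def write_spectra_csv(s: SpectrumSet, path) -> None:
    """Write the same dialect :func:`read_spectra_csv` consumes."""
    labels = [format(w, "g") for w in s.wavelengths]
    out = pd.concat(
        [s.meta.reset_index(drop=True),
         pd.DataFrame(s.reflectance, columns=labels)],
        axis=1,
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operators (all row-independent)


def splice_correct(s: SpectrumSet, boundaries=(1000.0, 1800.0)) -> SpectrumSet:
    """Remove detector-junction steps by additive segment offsetting.

    For each boundary (ascending), the segment starting at the boundary (and
    everything beyond it) is shifted so that its first value equals the linear
    extrapolation from the last two points of the preceding segment.
    """
    w = s.wavelengths
    x = s.reflectance.copy()
    for b in sorted(boundaries):
        idx = np.flatnonzero(w == b)
        if idx.size == 0:
            raise ValueError(f"splice boundary {b} nm is not on the wavelength grid")
        i = int(idx[0])
        if i < 2 or i >= len(w):
            raise ValueError(f"boundary {b} nm must be interior with two points before it")
        # linear extrapolation from the two grid points preceding the boundary
        slope = (x[:, i - 1] - x[:, i - 2]) / (w[i - 1] - w[i - 2])
        predicted = x[:, i - 1] + slope * (w[i] - w[i - 1])
        offset = predicted - x[:, i]
        x[:, i:] += offset[:, None]
    return s.with_data(reflectance=x)


def bin_to_10nm(s: SpectrumSet) -> SpectrumSet:
    """Average the 350–2500 nm 1-nm grid into 215 ten-nm bins.

    Bin k covers [350 + 10k, 360 + 10k) nm; the trailing 2500 nm point is
    folded into the last bin (11 members).  Output labels are the mean member
    wavelengths; output values the arithmetic member means.
    """
    w = s.wavelengths
    expected = np.arange(350, 2501)
    if w.size != expected.size or not np.array_equal(w, expected):
        raise ValueError("binning expects the 1-nm grid covering 350-2500 nm")
    bins = np.minimum(((w - 350) // 10).astype(int), 214)
    n_bins = 215
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    centers = np.bincount(bins, weights=w, minlength=n_bins) / counts
    summed = np.zeros((s.n_rows, n_bins))
    np.add.at(summed.T, bins, s.reflectance.T)
    return SpectrumSet(wavelengths=centers, reflectance=summed / counts, meta=s.meta)


def msc_correct(s: SpectrumSet, reference: np.ndarray | None = None) -> SpectrumSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference (default: column-wise mean
    spectrum), ``x_i ~ a_i + b_i * ref``; the corrected row is
    ``(x_i - a_i) / b_i``.  A near-zero slope is a degenerate scatter fit and
    is rejected with the offending row indices.
    """
    x = s.reflectance
    if reference is None:
        if s.n_rows < 2:
            raise ValueError("MSC needs >= 2 rows when no reference is given")
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("constant reference spectrum")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * reference.mean()
    bad = np.flatnonzero(np.abs(b) < 1e-8)
    if bad.size:
        raise ValueError(f"degenerate MSC fit (|b| < 1e-8) for rows {bad.tolist()}")
    return s.with_data(reflectance=(x - a[:, None]) / b[:, None])


def _sg_edge_kernel(n_left: int, n_right: int, order: int, at: int) -> np.ndarray:
    """Least-squares polynomial kernel on an asymmetric window.

    Fits an ``order``-degree polynomial to the points at offsets
    ``-n_left .. n_right`` and evaluates it at offset ``at``.
    """
    offsets = np.arange(-n_left, n_right + 1, dtype=float)
    v = np.vander(offsets, order + 1, increasing=True)
    # row of the hat matrix for the evaluation offset
    coef = np.linalg.lstsq(v, np.eye(len(offsets)), rcond=None)[0]
    powers = np.array([float(at) ** k for k in range(order + 1)])
    return powers @ coef


def savitzky_golay(s: SpectrumSet, window: int = 11, order: int = 2) -> SpectrumSet:
    """Savitzky–Golay smoothing with truncated-window edge handling.

    Interior points use the standard symmetric convolution kernel; each edge
    point is smoothed by fitting the polynomial on its truncated asymmetric
    window (no padding), so an exact degree-``order`` polynomial row is
    reproduced everywhere.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    p = s.n_bands
    if window > p:
        raise ValueError("window exceeds band count")
    half = window // 2
    x = s.reflectance
    kernel = savgol_coeffs(window, order)
    out = np.empty_like(x)
    # interior via correlation with the symmetric kernel
    from numpy.lib.stride_tricks import sliding_window_view

    out[:, half:p - half] = sliding_window_view(x, window, axis=1) @ kernel[::-1]
    for i in range(half):
        k_lo = _sg_edge_kernel(i, min(half, p - 1 - i), order, at=0)
        out[:, i] = x[:, : i + min(half, p - 1 - i) + 1] @ k_lo
        j = p - 1 - i
        k_hi = _sg_edge_kernel(min(half, j), i, order, at=0)
        out[:, j] = x[:, j - min(half, j): j + i + 1] @ k_hi
    return s.with_data(reflectance=out)


def preprocess(s: SpectrumSet, config: PreprocessConfig = PreprocessConfig()) -> SpectrumSet:
    """Apply the configured chain: splice -> bin -> (MSC) -> (Savitzky–Golay)."""
    out = splice_correct(s, config.splice_boundaries)
    out = bin_to_10nm(out)
    if config.apply_msc:
        out = msc_correct(out)
    if config.apply_sg:
        out = savitzky_golay(out, config.sg_window, config.sg_order)
    return out
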