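"""Splice correction, binning, MSC and Savitzky–Golay operators."""

import numpy as np
import pandas as pd
import pytest

from fieldspec.preprocess import (
    META_COLUMNS,
    PreprocessConfig,
    SpectrumSet,
    bin_to_10nm,
    msc_correct,
    read_spectra_csv,
    savitzky_golay,
    splice_correct,
    write_spectra_csv,
)
from fieldspec.simulate import WAVELENGTH_GRID


def _sset(matrix, wavelengths=None):
    matrix = np.atleast_2d(matrix)
    if wavelengths is None:
        wavelengths = WAVELENGTH_GRID.astype(float)
    meta = pd.DataFrame({
        "spot": range(len(matrix)), "plot": 0, "block": 0,
        "main": "NO", "sub": "CTR", "x": 0.0, "y": 0.0,
    })
    return SpectrumSet(wavelengths=wavelengths, reflectance=matrix, meta=meta)


# -- CSV round trip ---------------------------------------------------------

def test_csv_roundtrip(tmp_path, synthetic_spectrumset):
    path = tmp_path / "spectra.csv"
    write_spectra_csv(synthetic_spectrumset, path)
    back = read_spectra_csv(path)
    assert back.n_rows == 480 and back.n_bands == 2151
    np.testing.assert_allclose(back.reflectance, synthetic_spectrumset.reflectance, atol=1e-12)
    np.testing.assert_array_equal(back.wavelengths, synthetic_spectrumset.wavelengths)


def test_csv_single_row(tmp_path, synthetic_spectrumset):
    s = synthetic_spectrumset
    one = SpectrumSet(s.wavelengths, s.reflectance[:1], s.meta.iloc[:1])
    path = tmp_path / "one.csv"
    write_spectra_csv(one, path)
    assert read_spectra_csv(path).n_rows == 1


def test_csv_shuffled_wavelength_header_rejected(tmp_path):
    s = _sset(np.linspace(0.1, 0.5, 2151))
    path = tmp_path / "bad.csv"
    write_spectra_csv(s, path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    cols[7], cols[8] = cols[8], cols[7]
    df[cols].to_csv(path, index=False)
    with pytest.raises(ValueError, match="increasing"):
        read_spectra_csv(path)


# -- splice correction ------------------------------------------------------

def test_splice_continuous_spectrum_unchanged():
    """A globally linear spectrum is exactly invariant; a smooth curved one
    moves only by the (tiny) curvature error of the linear extrapolation."""
    w = WAVELENGTH_GRID.astype(float)
    linear = 0.1 + 2e-4 * (w - 350)
    out = splice_correct(_sset(linear))
    np.testing.assert_allclose(out.reflectance[0], linear, atol=1e-12)
    smooth = 0.2 + 0.1 * np.sin(w / 300.0)
    out2 = splice_correct(_sset(smooth))
    np.testing.assert_allclose(out2.reflectance[0], smooth, atol=1e-5)


def test_splice_removes_constructed_step():
    w = WAVELENGTH_GRID.astype(float)
    linear = 0.1 + 1e-4 * (w - 350)
    stepped = linear + 0.05 * (w >= 1000)
    out = splice_correct(_sset(stepped))
    assert np.abs(out.reflectance[0] - linear).max() < 1e-9


def test_splice_locality_of_second_boundary():
    w = WAVELENGTH_GRID.astype(float)
    linear = 0.1 + 1e-4 * (w - 350)
    stepped = linear + 0.05 * (w >= 1800)
    out = splice_correct(_sset(stepped))
    seg = (w >= 1000) & (w < 1800)
    np.testing.assert_allclose(out.reflectance[0][seg], linear[seg], atol=1e-12)
    assert np.abs(out.reflectance[0] - linear).max() < 1e-9


def test_splice_off_grid_boundary_rejected():
    s = _sset(np.full(2151, 0.3))
    with pytest.raises(ValueError, match="grid"):
        splice_correct(s, boundaries=(1000.5,))


# -- binning ----------------------------------------------------------------

def test_binning_band_count_and_constant():
    s = _sset(np.full(2151, 0.3))
    out = bin_to_10nm(s)
    assert out.n_bands == 215
    np.testing.assert_allclose(out.reflectance, 0.3, atol=1e-15)


def test_binning_closed_form_means():
    """Reflectance = wavelength/10000 bins to the mean member wavelength."""
    w = WAVELENGTH_GRID.astype(float)
    out = bin_to_10nm(_sset(w / 10000.0))
    np.testing.assert_allclose(out.reflectance[0], out.wavelengths / 10000.0, atol=1e-12)
    # last bin folds 2500 nm in: mean of 2490..2500 inclusive
    assert out.wavelengths[-1] == pytest.approx(2495.0)
    assert out.wavelengths[0] == pytest.approx(354.5)


def test_binning_conserves_grand_mean_of_full_bins(synthetic_spectrumset):
    out = bin_to_10nm(synthetic_spectrumset)
    w = synthetic_spectrumset.wavelengths
    full = w <= 2489
    assert out.reflectance[:, :214].mean() == pytest.approx(
        synthetic_spectrumset.reflectance[:, full].mean(), abs=1e-12
    )


def test_binning_rejects_non_unit_grid():
    s = _sset(np.full(215, 0.3), wavelengths=np.arange(350.0, 2500.0, 10.0)[:215])
    with pytest.raises(ValueError, match="1-nm"):
        bin_to_10nm(s)


# -- MSC --------------------------------------------------------------------

def test_msc_reference_row_unchanged(rng):
    ref = 0.2 + 0.1 * np.sin(np.linspace(0, 6, 215))
    rows = np.vstack([ref, 0.05 + 1.5 * ref, ref + 0.02 * rng.standard_normal(215)])
    out = msc_correct(_sset(rows, wavelengths=np.arange(215.0)), reference=ref)
    np.testing.assert_allclose(out.reflectance[0], ref, atol=1e-12)
    np.testing.assert_allclose(out.reflectance[1], ref, atol=1e-10)


def test_msc_is_idempotent(rng):
    """On scatter-model data (a_i + b_i * common shape + noise) a second MSC
    pass changes nothing."""
    common = 0.3 + 0.1 * np.sin(np.linspace(0, 5, 215))
    a = rng.normal(0, 0.05, size=8)
    b = rng.normal(1.0, 0.2, size=8)
    rows = a[:, None] + b[:, None] * common + 0.003 * rng.standard_normal((8, 215))
    s = _sset(rows, wavelengths=np.arange(215.0))
    once = msc_correct(s)
    twice = msc_correct(once)
    np.testing.assert_allclose(twice.reflectance, once.reflectance, atol=1e-4)


def test_msc_degenerate_slope_rejected():
    ref = np.linspace(0.1, 0.5, 215)
    rows = np.vstack([ref, np.full(215, 0.3)])  # constant row: b ~ 0
    with pytest.raises(ValueError, match="degenerate"):
        msc_correct(_sset(rows, wavelengths=np.arange(215.0)), reference=ref)


# -- Savitzky–Golay ---------------------------------------------------------

def test_sg_reproduces_quadratic_everywhere():
    x = np.arange(215.0)
    quad = 0.1 + 0.01 * x - 3e-5 * x**2
    out = savitzky_golay(_sset(quad, wavelengths=x), window=11, order=2)
    np.testing.assert_allclose(out.reflectance[0], quad, atol=1e-10)


def test_sg_constant_unchanged():
    out = savitzky_golay(_sset(np.full(215, 0.4), wavelengths=np.arange(215.0)))
    np.testing.assert_allclose(out.reflectance, 0.4, atol=1e-12)


def test_sg_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        savitzky_golay(_sset(np.full(215, 0.4), wavelengths=np.arange(215.0)), window=10)


def test_sg_noise_variance_shrinks_by_kernel_norm():
    """Interior smoothing factor equals the kernel's sum of squared weights."""
    from scipy.signal import savgol_coeffs

    factor = float((savgol_coeffs(11, 2) ** 2).sum())
    rng = np.random.default_rng(99)
    ratios = []
    for _ in range(100):
        noise = rng.standard_normal(215)
        out = savitzky_golay(_sset(noise, wavelengths=np.arange(215.0)))
        ratios.append(out.reflectance[0][5:-5].var() / noise.var())
    assert np.mean(ratios) == pytest.approx(factor, rel=0.10)


# -- cross-cutting properties ----------------------------------------------

@pytest.mark.parametrize("op", [
    lambda s: splice_correct(s),
    lambda s: bin_to_10nm(s),
    lambda s: msc_correct(s),
])
def test_operators_are_row_independent(op, synthetic_spectrumset, rng):
    s = SpectrumSet(
        synthetic_spectrumset.wavelengths,
        synthetic_spectrumset.reflectance[:20],
        synthetic_spectrumset.meta.iloc[:20],
    )
    perm = rng.permutation(20)
    permuted = SpectrumSet(s.wavelengths, s.reflectance[perm], s.meta.iloc[perm])
    a = op(s).reflectance[perm]
    b = op(permuted).reflectance
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(sg_window=4)
    with pytest.raises(ValueError):
        PreprocessConfig(sg_window=3, sg_order=5)
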