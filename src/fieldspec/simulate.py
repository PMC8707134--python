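"""Synthetic trial data with known ground truth.

Three layers are generated, each separately seeded from one master seed so a
stage can be regenerated independently:

* a zero-mean Gaussian random field on the spot coordinates whose covariance
  follows a :class:`~fieldspec.variogram.VariogramModel` (exact simulation via
  Cholesky factorization — no approximation);
* a per-spot response ``grand mean + main + sub + interaction + field`` with
  sum-to-zero effect adjustments, the ground truth attached for recovery
  tests;
* 2151-band reflectance spectra on the 350–2500 nm grid, driven by three
  latent score fields through smooth loading shapes located in the SWIR water
  bands (1450/1885/1940 nm), the NIR structural plateau (715–1375 nm) and the
  VIS pigment region (495/650 nm), plus small white noise.

Default magnitudes mirror the scales reported for real leaf-reflectance plot
trials: nugget variance around 0.26–0.9, partial sill 0.02–0.11, range
2.8–11.2 m, and treatment differences of 0.2–0.6 on the component scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fieldspec.design import TrialDesign, generate_design
from fieldspec.variogram import VariogramModel

__all__ = [
    "EffectSpec",
    "simulate_spatial_field",
    "compose_response",
    "synthesize_spectra",
    "default_effect_spec",
    "simulate_trial",
]

WAVELENGTH_GRID = np.arange(350, 2501)  # 1-nm grid, 2151 bands

_SUM_TOL = 1e-8


@dataclass(frozen=True)
class EffectSpec:
    """Fixed-effect structure plus residual variogram(s) for one response.

    ``main_effects``/``sub_effects``/``interaction_effects`` are adjustments
    around ``grand_mean`` and must each sum to zero (an identifiable
    parameterization, so recovery tests have unambiguous truth).
    ``variograms`` maps a main-factor level to its residual model for
    heteroscedastic scenarios, or the key ``None`` to a single shared model.
    """

    grand_mean: float
    main_effects: dict
    sub_effects: dict
    interaction_effects: dict
    variograms: dict

    def __post_init__(self) -> None:
        for name, d in (("main", self.main_effects), ("sub", self.sub_effects),
                        ("interaction", self.interaction_effects)):
            if d and abs(sum(d.values())) > _SUM_TOL:
                raise ValueError(f"{name} adjustments must sum to zero")

    def cell_mean(self, main: str, sub: str) -> float:
        """Expected response for one (main, sub) cell."""
        return (
            self.grand_mean
            + self.main_effects.get(main, 0.0)
            + self.sub_effects.get(sub, 0.0)
            + self.interaction_effects.get((main, sub), 0.0)
        )


def simulate_spatial_field(
    locations: np.ndarray, model: VariogramModel, seed: int
) -> np.ndarray:
    """One exact draw of a zero-mean Gaussian field with covariance ``c(h)``.

    The full n x n covariance matrix is built and Cholesky-factorized; the
    nugget appears only on the diagonal.  A non-positive-definite matrix is
    rejected with a diagnostic rather than silently regularized.
    """
    locations = np.asarray(locations, dtype=float)
    cov = model.covariance_matrix(locations)
    if model.sill == 0:
        return np.zeros(locations.shape[0])
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance matrix not positive definite for {model!r} "
            f"(n={locations.shape[0]})"
        ) from exc
    rng = np.random.default_rng(seed)
    return chol @ rng.standard_normal(locations.shape[0])


def compose_response(design: TrialDesign, spec: EffectSpec, seed: int) -> pd.DataFrame:
    """Per-spot response = fixed cell mean + spatial residual draw.

    Returns the spot table with added columns ``response`` (observed),
    ``truth_mean`` (the noiseless cell mean) and ``truth_field`` (the residual
    draw).  With per-main-level variograms the group fields are drawn
    independently (zero cross-group covariance).
    """
    spots = design.spots
    missing_main = set(spots["main"]) - set(spec.main_effects) if spec.main_effects else set()
    missing_sub = set(spots["sub"]) - set(spec.sub_effects) if spec.sub_effects else set()
    if missing_main or missing_sub:
        raise ValueError(f"levels missing from spec: {missing_main | missing_sub}")

    mean = np.array([spec.cell_mean(m, s) for m, s in zip(spots["main"], spots["sub"])])

    field_draw = np.zeros(len(spots))
    if None in spec.variograms:
        field_draw = simulate_spatial_field(design.locations, spec.variograms[None], seed)
    else:
        missing = set(spots["main"]) - set(spec.variograms)
        if missing:
            raise ValueError(f"no variogram for main level(s) {missing}")
        for k, level in enumerate(sorted(spec.variograms)):
            idx = np.flatnonzero(spots["main"].to_numpy() == level)
            locs = design.locations[idx]
            field_draw[idx] = simulate_spatial_field(locs, spec.variograms[level], seed + 1000 + k)

    out = spots.copy()
    out["truth_mean"] = mean
    out["truth_field"] = field_draw
    out["response"] = mean + field_draw
    return out


# ---------------------------------------------------------------------------
# spectral synthesis


def _gauss(x, center, width):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def base_spectrum(wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
    """A smooth green-leaf-like reflectance curve on the given grid.

    Low VIS with a green bump, a sharp red edge to an NIR plateau, and SWIR
    water absorption dips near 1450 and 1940 nm.  This is a plausible shape
    for driving the preprocessing/PCA stages, not a biophysical model.
    """
    w = np.asarray(wavelengths, dtype=float)
    vis = 0.06 + 0.05 * _gauss(w, 550, 40)
    red_edge = 0.40 / (1.0 + np.exp(-(w - 710) / 18))
    dips = (
        0.16 * _gauss(w, 1450, 55)
        + 0.22 * _gauss(w, 1940, 70)
        + 0.08 * _gauss(w, 2500, 200)
    )
    return np.clip(vis + red_edge - dips, 0.01, 0.99)


def loading_shapes(wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
    """Three smooth latent loading shapes (bands x 3), unit max amplitude.

    Column 0: SWIR water/biochemistry — a broad envelope over 1400–2500 nm
    with peaks at 1450, 1885 and 1940 nm and small plateaus near 2080 and
    2365 nm; column 1: the NIR structural plateau 715–1375 nm; column 2: VIS
    pigments — an envelope over 350–715 nm with peaks at 495 and 650 nm.
    The envelopes jointly cover the whole grid so that, as in measured leaf
    spectra, nearly every band is dominated by one latent factor.
    """
    w = np.asarray(wavelengths, dtype=float)
    swir = 0.55 / (1.0 + np.exp(-(w - 1395) / 30)) + (
        0.45 * _gauss(w, 1450, 60)
        + 0.35 * _gauss(w, 1885, 45)
        + 0.40 * _gauss(w, 1940, 55)
        + 0.15 * _gauss(w, 2080, 40)
        + 0.15 * _gauss(w, 2365, 30)
    )
    nir = 1.0 / ((1.0 + np.exp(-(w - 715) / 25)) * (1.0 + np.exp((w - 1375) / 40)))
    nir = nir * (0.8 + 0.1 * _gauss(w, 970, 35) + 0.1 * _gauss(w, 1200, 40))
    vis = 0.5 / (1.0 + np.exp((w - 715) / 25)) + (
        0.50 * _gauss(w, 495, 40) + 0.45 * _gauss(w, 650, 40)
    )
    shapes = np.column_stack([swir, nir, vis])
    return shapes / shapes.max(axis=0)


def synthesize_spectra(
    latents: np.ndarray,
    seed: int,
    amplitudes: tuple = (0.030, 0.027, 0.024),
    noise_sd: float = 0.001,
    noise_scale_nm: float = 15.0,
    splice_step_sd: float = 0.004,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
):
    """Build reflectance rows from three latent score vectors.

    ``reflectance = base + sum_k latent_k * amplitude_k * shape_k + noise +
    detector steps``, clipped to (0, 1).  The instrument noise is smooth in
    wavelength (white noise filtered at ``noise_scale_nm``), as produced by a
    scanning spectroradiometer; ``splice_step_sd`` adds per-row additive
    offsets to the detector segments starting at 1000 and 1800 nm, emulating
    the detector-junction steps that splice correction removes.  Returns an
    (n, bands) array; callers attach metadata via
    :class:`~fieldspec.preprocess.SpectrumSet`.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    if latents.shape[1] != 3:
        raise ValueError("expected exactly three latent score vectors (n x 3)")
    w = np.asarray(wavelengths, dtype=float)
    shapes = loading_shapes(w)
    base = base_spectrum(w)
    signal = (latents * np.asarray(amplitudes)) @ shapes.T
    rng = np.random.default_rng(seed)
    n = latents.shape[0]
    if noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        white = rng.standard_normal((n, w.size))
        smooth = gaussian_filter1d(white, noise_scale_nm, axis=1, mode="reflect")
        # unit-variance renormalization of the filtered noise
        smooth /= np.sqrt(1.0 / (2.0 * noise_scale_nm * np.sqrt(np.pi)))
        noise = noise_sd * smooth
    else:
        noise = 0.0
    steps = np.zeros((n, w.size))
    if splice_step_sd > 0:
        for boundary in (1000.0, 1800.0):
            steps[:, w >= boundary] += splice_step_sd * rng.standard_normal(n)[:, None]
    return np.clip(base + signal + noise + steps, 1e-6, 1.0 - 1e-6)


# ---------------------------------------------------------------------------
# ready-made scenarios


def default_effect_spec(
    component: int = 0,
    with_effects: bool = True,
    main_levels=("NO", "YES"),
    sub_levels=("TRI", "LAM", "CER", "CHE", "CTR"),
) -> EffectSpec:
    """The study-condition scenario for one latent component.

    Component 0 (SWIR/water-like) carries a heteroscedastic residual: a pure
    nugget for main level NO (sigma0=0.259) and a short-range spherical model
    for YES (sigma0=0.256, sigma=0.100, rho=2.77 m).  Component 1 (NIR-like)
    is pure nugget (0.917); component 2 (VIS-like) is a weak long-range
    spherical (0.556/0.022/11.19 m).  Treatment differences are at the
    0.2–0.6 scale, with the chemical-standard level (CHE) set 0.376 above the
    untreated control (CTR) on component 0.
    """
    if with_effects:
        main = {"NO": 0.1525, "YES": -0.1525}  # NO - YES = 0.305
        # CHE - CTR = 0.376; remaining levels intermediate
        sub = {"TRI": 0.060, "LAM": -0.045, "CER": -0.015, "CHE": 0.188, "CTR": -0.188}
        inter = {
            (m, s): 0.0 for m in main_levels for s in sub_levels
        }
    else:
        main = {m: 0.0 for m in main_levels}
        sub = {s: 0.0 for s in sub_levels}
        inter = {(m, s): 0.0 for m in main_levels for s in sub_levels}

    if component == 0:
        variograms = {
            "NO": VariogramModel("nugget", nugget=0.259),
            "YES": VariogramModel("spherical", nugget=0.256, psill=0.100, range_=2.77),
        }
    elif component == 1:
        variograms = {None: VariogramModel("nugget", nugget=0.917)}
    elif component == 2:
        variograms = {None: VariogramModel("spherical", nugget=0.556, psill=0.022, range_=11.19)}
    else:
        raise ValueError("component must be 0, 1 or 2")

    return EffectSpec(
        grand_mean=0.0,
        main_effects=main,
        sub_effects=sub,
        interaction_effects=inter,
        variograms=variograms,
    )


def simulate_trial(seed: int = 1, with_effects: bool = True, skew_component: int | None = None):
    """Generate a complete synthetic trial: design, three latent responses, spectra.

    Returns ``(design, responses, reflectance)`` where ``responses`` is the
    spot table with columns ``latent0..latent2`` (plus per-component truth)
    and ``reflectance`` is the (n, 2151) raw spectral matrix.  With
    ``skew_component`` set, that latent is exponentiated (then recentred),
    producing the strongly right-skewed marginal that triggers the rank-normal
    branch downstream.
    """
    design = generate_design(seed=seed)
    latents = []
    responses = design.spots.copy()
    for k in range(3):
        spec = default_effect_spec(component=k, with_effects=with_effects)
        resp = compose_response(design, spec, seed=seed * 7919 + k)
        z = resp["response"].to_numpy()
        if skew_component == k:
            z = np.exp(z)
            z = z - z.mean()
        responses[f"latent{k}"] = z
        responses[f"truth_mean{k}"] = resp["truth_mean"]
        latents.append(z)
    reflectance = synthesize_spectra(np.column_stack(latents), seed=seed * 7919 + 99)
    return design, responses, reflectance
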