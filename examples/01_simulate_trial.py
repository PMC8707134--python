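"""Generate a synthetic split-plot trial and write its spectra CSV.

The generator builds the trial geometry (4 blocks x 2 compost halves x 5
treatment plots, 12 spots each), draws three latent response fields with
known fixed effects and spatial covariance, and renders 2151-band spectra.
"""

from fieldspec.design import generate_design
from fieldspec.preprocess import META_COLUMNS, SpectrumSet, write_spectra_csv
from fieldspec.simulate import WAVELENGTH_GRID, simulate_trial

design = generate_design(seed=1)
print(f"plots: {design.n_plots}, spots: {design.n_spots}")
print(design.plots.head(3).to_string(index=False))

design, responses, reflectance = simulate_trial(seed=1)
print(f"reflectance matrix: {reflectance.shape[0]} spots x {reflectance.shape[1]} bands")
print(f"latent response SDs: "
      + ", ".join(f"{responses[f'latent{k}'].std():.3f}" for k in range(3)))

spectra = SpectrumSet(WAVELENGTH_GRID.astype(float), reflectance,
                      responses[META_COLUMNS].copy())
write_spectra_csv(spectra, "trial_spectra.csv")
print("wrote trial_spectra.csv (one row per spot: design columns + 2151 bands)")
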