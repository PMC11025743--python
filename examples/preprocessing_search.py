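"""Search spectral pre-treatments by cross-validated PLS error.

Simulates spectra with strong per-sample multiplicative scatter, then ranks
every admissible single- and two-step pre-treatment pipeline by RMSECV at
its optimal latent count.  Scatter corrections (SNV/MSC) should dominate
the top of the table because they remove exactly the distortion simulated.
"""

import silcal as sc

library = sc.default_library(seed=1)
recipe = sc.default_recipe(
    n_samples=40, seed=8,
    gain_range=(0.3, 3.0), offset_range=(-1.0, 1.0), noise_sd=0.005,
)
spectra, refs = sc.gen_spectra_dataset(library, recipe)

best, table = sc.search_pipelines(
    spectra.absorbance, refs.values_for("NDF"),
    wavelengths=spectra.wavelengths, max_len=2, nlv_max=6, seed=0,
)
print("top 8 pipelines by RMSECV (NDF, % DM):")
print(table.head(8).to_string(index=False))
print(f"\nwinner: {'(raw)' if best is None else best.tokens}")
# lower RMSECV = better; the winner is refit on all calibration data downstream
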