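"""Generate a two-class synthetic FT-MIR campaign and inspect its structure.

Builds 20 samples (12 cultivated, 8 wild) with 3 replicate scans each on a
4000 -> 450 cm^-1 grid, then prints the record bookkeeping and the band
positions where the classes differ most.
"""

import numpy as np

from mircos import SyntheticConfig, clean_class_spectrum, generate_spectra

cfg = SyntheticConfig(
    n_per_class={"cultivated": 12, "wild": 8},
    grid=(4000.0, 450.0, 2.0),
    seed=1,
)
spectra = generate_spectra(cfg)

print(f"records: {spectra.n_records} ({len(spectra.unique_sample_ids)} samples "
      f"x {spectra.replicate_count} replicate scans)")
print(f"grid: {spectra.wavenumbers[0]:.0f} -> {spectra.wavenumbers[-1]:.0f} cm^-1, "
      f"{spectra.n_wavenumbers} points")

wild = clean_class_spectrum(cfg, "wild")
cult = clean_class_spectrum(cfg, "cultivated")
w = cfg.wavenumbers
top = np.argsort(np.abs(wild - cult))[::-1][:3]
print("largest class differences (clean spectra):")
for i in sorted(top):
    print(f"  {w[i]:7.1f} cm^-1: wild {wild[i]:.3f} vs cultivated {cult[i]:.3f} AU")
# The classes share every band position; only band intensities differ —
# wild material is enriched in the amide/lipid bands and depleted in the
# 1014 cm^-1 carbohydrate band.
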