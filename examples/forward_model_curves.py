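"""Evaluate the two-layer diffuse skin model across the working bands.

Prints modeled reflectance spectra for a perfused (saturated) and an
occluded (desaturated) skin state.  Reflectance rises toward the red end
where hemoglobin absorbs weakly; the desaturated state is darker around
580-625 nm because deoxyhemoglobin absorbs more strongly there.
"""

import numpy as np

from oximap import DEFAULT_TARGET_BANDS, SkinParams, forward_reflectance
from oximap.optics import default_chromophore_table

table = default_chromophore_table()
bands = np.array(DEFAULT_TARGET_BANDS)

states = {
    "baseline (SO2=0.98)": SkinParams(B=2e-3, SO2=0.98, M=0.02, d_e_um=90),
    "occluded (SO2=0.35)": SkinParams(B=4e-3, SO2=0.35, M=0.02, d_e_um=90),
}

print("band_nm   " + "   ".join(f"{name:>20s}" for name in states))
spectra = {name: forward_reflectance(p, bands, table)
           for name, p in states.items()}
for i, b in enumerate(bands):
    row = "   ".join(f"{spectra[name][i]:20.4f}" for name in states)
    print(f"{b:7.0f}   {row}")

print("\nEach column is absolute diffuse reflectance (fraction of incident"
      "\nlight) at the band center; the occluded column dips hardest where"
      "\ndeoxyhemoglobin dominates absorption.")
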