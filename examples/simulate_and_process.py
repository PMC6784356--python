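"""Full pipeline on a synthetic mottled-skin phantom.

Simulates a two-patch phantom (a desaturated mottled patch next to
well-perfused skin) through the complete acquisition chain — illumination
gains, channel cross-talk, shot/read noise, 10-bit mosaic snapshot — then
runs demosaic, unmixing, reflectance calibration, band selection, ROI
masking, k-means segmentation (K=10) and per-cluster model inversion.
"""

import numpy as np

from oximap import NoiseModel, PhantomSpec, SkinParams, simulate_phantom
from oximap.optics import default_chromophore_table
from oximap.pipeline import PipelineConfig, process_frames
from oximap.preprocess import central_crop_slice

table = default_chromophore_table()
common = dict(M=0.02, d_e_um=90.0)
spec = PhantomSpec(
    patches=[SkinParams(B=4e-3, SO2=0.35, **common),   # mottled patch
             SkinParams(B=2e-3, SO2=0.85, **common)],  # perfused skin
    fractions=[0.4, 0.6], noise=NoiseModel(), seed=42)

raw, white, dark, truth = simulate_phantom(spec, table)
print(f"simulated raw mosaic frame: {raw.pixels.shape}, "
      f"max count {int(raw.pixels.max())} of 1023")

config = PipelineConfig(fix_melanin=0.02, fix_thickness=90.0, seed=1)
result = process_frames(raw, white, dark, spec.resolved_sensitivity(),
                        table, config)
sat = result.saturation

h, w = truth.label_map.shape
labels = truth.label_map[:, central_crop_slice(h, w)]
print(f"\nSO2 mean = {sat.so2_mean:.1f} %   mottling SD = {sat.so2_sd:.1f} %")
for k, p in enumerate(spec.patches):
    m = (labels == k) & sat.roi_mask
    print(f"patch {k}: true SO2 {100 * p.SO2:5.1f} %   "
          f"recovered {np.nanmean(sat.so2_map[m]):5.1f} %")
print("\nThe mottling SD is the area-weighted dispersion of cluster SO2 —"
      "\nlarge here because the phantom mixes desaturated and saturated"
      "\npatches, the spectral signature of mottled skin.")
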