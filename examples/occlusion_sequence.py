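"""Synthetic arterial-occlusion sequence: baseline -> occlusion -> hyperemia.

Reproduces the qualitative trajectory of a cuff-occlusion provocation:
the area-weighted mean SO2 collapses during occlusion and recovers with
post-occlusive hyperemia, while the mottling index (weighted SD of cluster
SO2) peaks mid-sequence when the skin is patchiest.
"""

from oximap import occlusion_series, simulate_phantom
from oximap.optics import default_chromophore_table
from oximap.pipeline import PipelineConfig, process_frames

table = default_chromophore_table()
config = PipelineConfig(fix_melanin=0.02, fix_thickness=90.0, seed=2)

print(f"{'stage':<12} {'SO2 mean [%]':>12} {'mottling SD [%]':>16}")
for name, spec in zip(("baseline", "occlusion", "hyperemia"),
                      occlusion_series(base_seed=3)):
    raw, white, dark, _ = simulate_phantom(spec, table)
    result = process_frames(raw, white, dark, spec.resolved_sensitivity(),
                            table, config)
    sat = result.saturation
    print(f"{name:<12} {sat.so2_mean:>12.1f} {sat.so2_sd:>16.1f}")

print("\nMean saturation falls then recovers; the mottling index peaks in"
      "\nthe occluded stage — the hyperspectral signature of skin mottling.")
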