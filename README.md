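# oximap

Skin oxygen-saturation mapping from snapshot-mosaic hyperspectral images.

`oximap` re-implements, as a tested Python library and CLI, the processing
chain of a real-time hyperspectral skin oximeter: a 16-channel 4 × 4
mosaic snapshot camera observes skin in the 470–630 nm range, and the
software turns each raw frame into a segmented map of hemoglobin oxygen
saturation (SO₂) plus two scalar diagnostics — the area-weighted mean SO₂
and a *mottling index* quantifying how patchy the saturation is. It is
aimed at biomedical-optics researchers who want to study or extend this
kind of pipeline without the camera hardware: a synthetic phantom
generator built on the same forward physics replaces the device, so every
stage is testable at desk scale.

## Pipeline and model

Raw frame → demosaic (16-band cube) → spectral unmixing (pseudo-inverse of
the collapsed sensor sensitivity matrix) → reflectance calibration
`R = 0.99 (I − I_dark)/(I_white − I_dark)` → selection of ten working
bands (507–625 nm) → central crop + circular ROI → k-means segmentation
(K = 10) of the ROI spectra → per-cluster inversion of a two-layer diffuse
optical skin model → SO₂ map and diagnostics.

The optical model treats skin as a melanin-bearing epidermis of thickness
d_e over a semi-infinite blood-perfused dermis, with

* µ_a(λ) = M µ_mel + B·SO₂·µ_oxy + B(1−SO₂)·µ_deoxy,
* µ′_s(λ) = µ′_s500 [f_Ray (λ/500)⁻⁴ + (1−f_Ray)(λ/500)^(−b_Mie)],

and diffuse reflectance from the two-layer diffusion approximation
(auxiliaries ς = 1/(3(µ′_s+µ_a)), δ = 1/√(3µ_a(µ′_s+µ_a))). Inversion is
bounded multi-start nonlinear least squares for (B, SO₂, M, d_e); the
cluster diagnostics are SO₂_mean = Σ wᵢ SO₂ᵢ and the weighted standard
deviation SO₂_SD = √(K/(K−1) Σ wᵢ(SO₂ᵢ−SO₂_mean)²) with wᵢ the cluster
area fractions. See `docs/methods.md` for the full derivation and every
numerical choice.

## Worked example

`examples/simulate_and_process.py` simulates a two-patch mottled-skin
phantom through the full acquisition chain (illumination gains, channel
cross-talk, shot/read noise, 10-bit mosaic snapshot) and runs the complete
pipeline on it:

```
simulated raw mosaic frame: (1088, 2048), max count 430 of 1023

SO2 mean = 68.9 %   mottling SD = 25.0 %
patch 0: true SO2  35.0 %   recovered  35.1 %
patch 1: true SO2  85.0 %   recovered  85.1 %
```

The two recovered values are the mean of the segmented SO₂ map over each
ground-truth patch: the desaturated ("mottled") patch and the perfused
patch are both recovered to a fraction of a percentage point despite
sensor noise, and the large mottling SD reflects the patchy scene.
`examples/occlusion_sequence.py` plays a three-stage arterial-occlusion
scenario and prints the characteristic trajectory (mean SO₂ falls from
≈98 % to ≈43 % and recovers; the mottling index peaks mid-sequence);
other examples cover the forward model, single-spectrum fitting, and the
unmixing quality metric.

The same flows are available from the shell:

```sh
oximap simulate --out ph --stage occlusion --seed 4
oximap process --raw ph/raw.tiff --white ph/white.tiff --dark ph/dark.tiff \
    --sensitivity ph/sensitivity.csv --out run --fix-melanin 0.02 --fix-thickness 90
oximap report --b 2e-3 --so2 0.8        # forward-model reflectance as CSV
oximap fit-spectrum --spectrum spec.csv # invert one measured spectrum
```

`process` writes `so2_map.tiff`/`.png`, `clusters.csv`, `fits.csv`,
`diagnostics.csv` and a `manifest.json` that records config, seeds and
library versions, sufficient to reproduce the run exactly.

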