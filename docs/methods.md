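# Methods

`oximap` estimates per-region skin oxygen saturation (SO₂) and a mottling
index from snapshot-mosaic hyperspectral frames. This note records the
models, the numerical choices, and what the synthetic phantom machinery
does and does not emulate.

## Processing chain

A raw 10-bit snapshot (default 1088 × 2048) carries a 4 × 4 mosaic of 16
Fabry–Pérot spectral channels. Processing order is fixed:

1. **Demosaic** — deinterleave into a 16-band cube (272 × 512 at the
   default geometry). The position→channel mapping (`band_layout`) is
   hardware-specific and must be declared; the default is row-major.
2. **Spectral unmixing** — per pixel, the raw channel vector is modeled as
   `M_mix · s` where `M_mix` is the sensor sensitivity matrix collapsed
   onto the 16 nominal channel centers (each row normalized to 1 at its
   own center). The true spectrum `s` is the minimum-norm least-squares
   solution (pseudo-inverse). Matrices with condition number above 10⁸ are
   rejected with the condition number in the error.
3. **Reflectance calibration** — `R = 0.99 · (I − I_dark)/(I_white − I_dark)`
   per pixel and band, against a 99 %-reflectance white standard and a
   dark frame. Because measurement and white share the per-pixel
   illumination, the ratio also flattens uneven illumination. The ratio is
   computed before the 0.99 multiplication so that measuring the white
   standard itself returns exactly 0.99. Pixels with `I_white ≤ I_dark`
   in any band are masked out; more than 1 % bad pixels aborts. R is
   clipped to [0, 1.5].
4. **Band selection** — the ten working bands 507, 518, 532, 544, 568,
   580, 593, 604, 617, 625 nm by nearest-center match (ambiguous matches
   are an error). These bands combine low inter-channel mixing with strong
   hemoglobin contrast.
5. **Crop and ROI** — central height × height square (272 × 272 default)
   with an inscribed circular region of interest
   (`(i−c)² + (j−c)² ≤ (side/2)²`, `c = (side−1)/2`). All statistics are
   restricted to the ROI.
6. **Segmentation** — k-means (K = 10 by default) on the ten-band ROI
   spectra, plain Euclidean distance, no spectral normalization. k-means++
   initialization, best of `n_init = 10` restarts, deterministic for a
   fixed seed. After the scikit-learn fit, a short Lloyd refinement loop
   runs until the assignment is stable, so each returned centroid is
   exactly the mean of its members; empty clusters are reseeded to the
   farthest point; assignment ties break to the lowest cluster index.
   Cluster area weights are `w_i = A_i / A_RoI`.
7. **Inversion** — the two-layer model (below) is fitted to each cluster
   centroid spectrum by bounded trust-region nonlinear least squares.
8. **Diagnostics** — cluster SO₂ broadcast to member pixels gives the
   segmented map; scalars are the weighted mean and the mottling index.

## Two-layer diffuse reflectance model

The skin is a melanin-bearing epidermis of thickness `d_e` (60–120 µm) on
a semi-infinite blood-perfused dermis. Per layer:

* absorption `µ_a = M·µ_mel + B·SO₂·µ_oxy + B·(1−SO₂)·µ_deoxy` (cm⁻¹),
  with `B = 0` in the epidermis and `M = 0` in the dermis;
* reduced scattering
  `µ′_s(λ) = µ′_s500 · [f_Ray (λ/500)⁻⁴ + (1−f_Ray)(λ/500)^(−b_Mie)]`,
  identical in both layers;
* diffusion auxiliaries `ς = 1/(3(µ′_s + µ_a))` (diffusion constant, one
  third of the transport mean free path) and
  `δ = 1/√(3 µ_a (µ′_s + µ_a))` (penetration depth), both in cm.

Defaults (fixed during inversion): `µ′_s500 = 48 cm⁻¹`, `f_Ray = 0.4`,
`b_Mie = 0.7`, boundary parameter `A = 0.2`.

Reflectance comes from the one-dimensional diffusion approximation with an
exponentially attenuated collimated source: unit irradiance decays with
the transport coefficient `1/(3ς)` and feeds an isotropic source
`µ′_s · exp(−z/(3ς))`; the diffuse fluence φ satisfies
`ς φ'' = µ_a φ − source` in each layer, with

* partial-current surface condition `A·φ(0) = ς_e·φ′(0)`
  (equivalent to `A = (1−R_eff)/(2(1+R_eff))`, so `A = 0.2` corresponds to
  an effective internal reflection of ≈ 0.43, typical of a tissue–air
  interface),
* continuity of fluence and diffuse flux at the layer interface,
* boundedness in the semi-infinite dermis.

Under that boundary condition the escaping diffuse flux equals `A·φ(0)`,
which is the returned reflectance. The three remaining solution
coefficients form a 3 × 3 linear system per wavelength; the growing
epidermal mode is rescaled by `exp(−d_e/δ_e)` so the system stays
well-conditioned at every admissible parameter combination. This
construction guarantees the model's defining limits *exactly*: identical
layer optics make R independent of `d_e`; large `d_e` converges to the
semi-infinite epidermis value; R is finite and in (0, 1) over the whole
admissible box and non-increasing in B.

Numerical details: the particular solution's denominator
`1/δ² − 1/ℓ² = µ_tr(3µ_a − µ_tr)` has a removable zero at `µ′_s = 2µ_a`
(reachable for melanin fractions near 0.09); it is floored at
`10⁻⁸·µ_tr` in magnitude, introducing relative errors far below every
tolerance used. `µ_a = 0` exactly is rejected (`δ` undefined); the dermis
absorption is floored at 10⁻¹² cm⁻¹ so `B → 0` stays evaluable. The
melanin fraction is clamped to [10⁻³, 0.5] with a logged warning — a
volume fraction above ~0.5 is unphysical even though wider ranges
circulate in parameter tables.

## Chromophore data

The bundled table (`data/chromophores_synthetic.csv`, 450–650 nm at 1 nm)
is a **synthetic approximation** of the standard hemoglobin/melanosome
compilations: monotone-cubic (PCHIP) interpolation through ~28 landmark
molar extinction values that pin the well-known features — isosbestic
points near 500/529/545/570/585 nm, the oxyhemoglobin double peak at
540/576 nm, the deoxyhemoglobin peak at 555 nm, and the steep
oxyhemoglobin fall-off beyond 585 nm — scaled to whole blood at
150 g hemoglobin/L (`µ = ln10 · ε · 150/64500`). Melanosome absorption is
the standard power law `1.70·10¹² λ⁻³·⁴⁸ cm⁻¹`. Users with a measured
table can supply their own CSV; lookups interpolate linearly and refuse to
extrapolate. Because phantoms are rendered and inverted with the same
table, every quantitative result in the test suite depends only on the
table's qualitative shape, not its metrological accuracy.

## Inversion

Loss is the sum of squared reflectance residuals over the ten bands, as in
an `lsqcurvefit`-style bounded fit. Free parameters default to
(B, SO₂, M, d_e) with bounds B ∈ [10⁻⁸, 10⁻²], SO₂ ∈ [0, 1],
M ∈ [10⁻³, 0.5], d_e ∈ [60, 120] µm; B is optimized in log₁₀ space because
its range spans six decades and its accuracy contract is relative. The
optimizer is scipy's trust-region reflective least squares
(`x_scale="jac"`, `ftol = 10⁻¹⁰`, `xtol = 10⁻⁸`), multi-started from a
seeded Latin-hypercube of 8 interior points (plus the user's initial guess
when given); the best incumbent by loss is returned, flagged when not
converged. The full 4-parameter problem is under-determined from ten
bands; the pipeline therefore supports fixing M and d_e (`--fix-melanin`,
`--fix-thickness`), which is the configuration used for quantitative
recovery claims. Degenerate inputs (an all-zero spectrum) return a flagged
non-converged result rather than raising.

## Diagnostics

`SO₂_mean = Σ w_i SO₂_i` over clusters. The mottling index is the
area-weighted standard deviation

`SO₂_SD = sqrt( K/(K−1) · Σ w_i (SO₂_i − SO₂_mean)² )`

over the K non-empty clusters (weight-0 clusters do not enter K). The
weighted *first* moment of deviations is identically zero whenever the
weights sum to one, so a dispersion statistic necessarily carries the
square and root; K/(K−1) debiases the K-cluster average in analogy with
the sample standard deviation, and K = 1 returns 0 by convention. Both
diagnostics are reported in percent. The ROI mean of the broadcast map
equals the weighted mean identically (same counting).

## Synthetic phantoms and the sensor simulator

Phantoms are piecewise-constant maps of (B, SO₂, M, d_e). Patch geometry
is either an explicit label image or "blobs": a Gaussian-smoothed white
noise field (smoothing scale 12 px by default, giving mottling-like
patches at the 272² working resolution) thresholded at quantiles so patch
area fractions are met to within discreteness. Scene reflectance is
rendered with the forward model once per patch at the 16 channel centers.

The sensor simulator applies the acquisition chain forward: per-band
illumination gains (two-LED model: cyan 505 nm/30 nm FWHM plus lime
568 nm/100 nm FWHM at 1/20 intensity ratio), channel mixing by the
collapsed sensitivity matrix, mosaic interleaving, exposure scaled so the
white target peaks at 850 counts, Gaussian shot noise with variance
`shot_scale · signal` (shot_scale = 0.08 DN/e⁻, the system gain implied by
a ~13.5 ke⁻ full well behind a 10-bit ADC), additive read noise
(σ = 2 DN), a dark offset (8 DN), and rounding to 10 bits. The white
reference frame images a uniform 0.99-reflectance target under the same
gains — the physical role of the spectralon standard — so the noiseless,
unquantized chain recovers the scene reflectance to machine precision,
and the quantized noiseless chain to within the rounding of the weakest
channels. Shot noise acts on the photo-signal only, so dark frames carry
just offset, read noise and quantization. All randomness flows from one
seed; identical spec + seed gives bit-identical frames.

The synthetic sensitivity fixture builds Gaussian main lobes (FWHM 15 nm)
with side lobes of configurable relative amplitude at the two adjacent
channel centers; every lobe is notched to vanish at the other channel
centers, so the collapsed mixing matrix is exactly
`I + crosstalk · adjacency` — diagonal at zero cross-talk and full-rank
for cross-talk below 0.5. The default channel grid places the ten working
bands at well-separated centers and concentrates the tight spacings in
the six spare channels, mirroring a sensor whose analysis bands are
chosen for minimal spectral mixing; this keeps unmixing from amplifying
noise into the working bands.

What the phantoms do **not** emulate: continuous (non-piecewise) parameter
variation, specular glare and polarization leakage, lens point-spread
blur, motion, chromatic focus shifts, and within-patch biological texture.
Passing the recovery tests therefore demonstrates correctness of the
algorithm chain under the stated sensor physics, not clinical accuracy on
real skin.

## Problem sizes and determinism

Default test and example runs use the full sensor geometry
(1088 × 2048 raw, ~58 000 ROI pixels, K = 10, 8 fit starts), which
processes in a few seconds; some unit tests use reduced frames where only
bookkeeping is at stake. Every stochastic component (phantom layouts,
sensor noise, k-means restarts, fit multi-starts) is seeded, and pipeline
reruns with the same configuration produce byte-identical tables.

## Known limitations

* The two-layer model shares one scattering law across layers and ignores
  anisotropy beyond the reduced-scattering description.
* Per-pixel (unclustered) inversion is out of scope; SO₂ is constant
  within a cluster by construction.
* The bundled chromophore table is a labelled synthetic stand-in (above);
  absolute SO₂ on real data requires a measured table and sensor
  sensitivities.
* The diffusion approximation degrades when absorption rivals scattering
  (deep-blue wavelengths, very high melanin); the working bands and
  parameter box keep it in its validity region, and the box is enforced.
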