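# Methods note

This note records the models, parameter choices and numerical
conventions behind the phantom generator and the measurement pipeline,
and the known limits of both.

## Phantom model

A phantom is a 3-D density volume on an isotropic grid, indexed
(z, y, x) with z the electron-beam axis. The canonical grid is
128 × 256 × 256 voxels at 0.7 nm/voxel (≈ 90 × 179 × 179 nm), matching
typical binned tomogram pixel sizes of lamella data.

Structures are additive density primitives:

* **Layers** (membranes, cellulose sheets, cortical-belt layers): slabs
  normal to the y (profile) axis, soft-edged by an error-function ramp
  of half-width 0.5 voxel so that sub-voxel positioning is meaningful.
  A layer may be laterally finite along x (finite-width sheets).
* **Cylinders** (microfibrils): soft-edged circular cross-sections swept
  along an arbitrary axis.

The canonical envelope geometry places, along y relative to the OM
centre (positive = extracellular): IM at −30 nm, three belt layers at
−54/−69/−84 nm (24 nm inside the IM, 15 nm apart), and, in the tight
configuration, two sheets at +16 and +32 nm. The loose variant has a
single sheet at +99 nm. Membranes are 6 nm thick with amplitude 1.0,
sheets 8 nm at 0.8, belt layers 6 nm at 0.7. The width variant renders
a laterally finite sheet (38 nm) and belt layer (47 nm); the fibril
variant renders an 11 nm diameter cylinder. Each rendered phantom
carries a ground-truth sidecar with every implied spacing and width.

These offsets and widths are the generator's *study conditions*: they
define what the pipeline must recover and are never adjusted to the
pipeline's performance.

## Imaging model

Applied in physical order:

1. **PSF blur** — isotropic Gaussian filter (σ in nm), a pragmatic proxy
   for defocus-dominated contrast transfer. Canonical σ = 2 nm.
2. **Missing wedge** — hard binary mask in Fourier space: coefficients
   with |k_perp| < |k_beam| · cot(tilt range) are zeroed, where k_perp
   is the in-plane frequency component perpendicular to the tilt axis.
   Canonical tilt range ±60°. The mask leaves the tilt-axis direction
   untouched, and (at these geometries) the profile-axis spacings, which
   is why measurement lines are laid along those directions.
3. **Additive white Gaussian noise** — σ defined through
   SNR = membrane amplitude / noise σ; canonical SNR = 2. Seeded via
   `numpy.random.default_rng`.

The identity model (no blur, full tilt, no noise) is used for the
width/diameter variants, whose FWHM reads are deterministic and defined
noise-free.

### Realism limits of the generator

* The hard wedge mask models the tilt-range support only — no CTF
  oscillation, no dose weighting, no per-tilt alignment error. The
  measured beam-axis/in-plane FWHM elongation of a blurred impulse is
  ≈ 1.46, below the theoretical 1.55 elongation factor (which describes
  a different functional of the PSF); the property tests assert the
  ratio lies in [1.4, 1.7].
* Gaussian blur stands in for the full CTF; its monotone widening of
  FWHM reproduces the qualitative defocus-overestimation effect only.
* Noise is white; real tomogram noise is correlated by reconstruction.
* The PSF uses wrap-around (periodic) boundaries, which conserve total
  density exactly; features are kept far from the volume edge.

## Measurement pipeline

* **Profile extraction**: trilinear interpolation
  (`scipy.ndimage.map_coordinates`, order 1) along the line, averaged
  over a rectangle of parallel lines (default 20 nm across, 10 nm deep
  toward the beam axis, one-voxel offset spacing). Sampling step
  defaults to half a voxel.
* **Normalization**: min-max to [0, 1]; constant profiles map to 0.5
  and are flagged degenerate.
* **Peak detection**: `scipy.signal.find_peaks` with prominence ≥ 0.1
  and ≥ 5 nm separation, then three-point parabolic refinement
  (sub-sample, clipped to ±0.5 sample; ties resolve to the lower index).
* **Peak labelling** is positional (belt layers, IM, OM, then sheets,
  cytoplasm → exterior). When the expected peak count is known, the
  `n_expected_peaks` parameter keeps only the N most prominent peaks
  before labelling; without it, a noise bump at exactly the prominence
  threshold can shift every positional label.
* **FWHM**: width at half prominence-height (level = peak height −
  prominence/2) with linear interpolation of the crossings; truncated
  peaks raise rather than return a biased value.
* **Classification**: loose iff OM-to-closest-sheet > 40 nm (strict).

Noise-free identity imaging recovers all canonical spacings within
0.35 nm (half a voxel). FWHM reads of soft-edged slabs and cylinders
carry a small geometric bias (the fibril read is ≈ 0.42 nm low, from
averaging chords across the circular cross-section within the averaging
rectangle); identity width checks therefore use a one-voxel (0.7 nm)
tolerance.

## Statistics

Sample sizes in this domain are tiny (3–45), so:

* **Mann-Whitney** is computed exactly by enumerating all C(n1+n2, n1)
  group assignments of the mid-ranked data (feasible for
  min(n) ≤ 10); larger samples fall back to the tie-corrected normal
  approximation and are flagged.
* **One-sample Wilcoxon signed-rank** uses the exact null distribution
  of the signed-rank sum (dynamic-programming convolution over doubled
  ranks, n ≤ 25); zero differences are dropped.
* **Dispatcher**: per-group Shapiro-Wilk gate (α = 0.05; groups with
  n < 3 or constant values are treated as non-normal) chooses between
  t-test / Welch (SD ratio > 2) / ANOVA + Tukey HSD and exact
  Mann-Whitney / Kruskal-Wallis + Dunn (Bonferroni).

## Recovery experiment

For each variant the pipeline renders replicates with seeds
`base_seed + 1 … base_seed + n` (n = 20 for the noisy tight/loose
variants, 1 for the deterministic width/fibril variants), measures them
with canonical lines placed from the known geometry, and reports mean,
bias, RMSE and a pass flag per quantity against fixed tolerances
(2 nm for envelope spacings, 5 nm for the loose distance, 3 nm for the
sheet width, 2 nm for the fibril diameter). Per-replicate measurement
failures are logged and counted rather than aborting the run; a row only
passes if every replicate succeeded.

## Limitations

* Phantoms are planar and noise-white; no membrane curvature, no
  crowding, no reconstruction artifacts beyond the wedge.
* Positional peak labelling assumes the annotated line crosses the
  stated number of belt layers and the two membranes in order; heavily
  disordered geometries require manual labelling.
* FWHM under blur is an upper bound on feature size by construction;
  no deconvolution is attempted.
* The lamella census treats cells as 2-D annotations on the lamella
  plane; occupancy is an area fraction, a proxy for volume fraction.
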