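# Methods

This note documents the models implemented in `oaskin`, the assumptions they
make, the tunable parameters and their defaults, and the design decisions
taken where several reasonable choices existed. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic layered-skin phantom

The phantom (`oaskin.phantom`) is a voxelized block of mouse skin viewed from
above: a water coupling gap, epidermis, dermis, dermal white adipose tissue
(dWAT), a thin vascular panniculus band, and subcutaneous fat to the bottom
of the box. Depth is axis 0 (positive downward), the fast scan axis is
axis 1 and the slow axis is axis 2; geometry is in mm. Axial voxels are
half-open intervals [k·dz, (k+1)·dz) with centers at (k+0.5)·dz; lateral
grids are sample points at k·dx with `floor(extent/step) + 1` samples, so a
4 × 2 mm field at 7.5 / 15 µm steps has 534 × 134 raster positions, matching
the emulated scanner.

**Layers.** Interfaces undulate conformally (one smooth low-frequency
lateral undulation shared by all interfaces, default amplitude 20 µm, period
1.5 mm), so configured layer thicknesses are exact — which is what makes the
phantom a usable oracle for thickness-recovery tests. Defaults (lean
mouse): 0.30 mm coupling gap, 30 µm epidermis, 0.35 mm dermis, 0.30 mm dWAT,
0.10 mm panniculus. The obese-sedentary group configuration thickens dWAT to
0.70 mm and leaves the dermis unchanged.

**Chromophores.** Each layer carries diffuse per-voxel baselines (arbitrary
concentration units) with ±50 % multiplicative heterogeneity emulating the
unresolved capillary bed and tissue texture: the epidermis carries a modest
blood signal (the surface line every skin scan shows), the dermis a
blood-rich bed (0.30 total hemoglobin) with some lipid and water, the
adipose layers are lipid-rich (1.0 dWAT, 0.9 scWAT) and nearly blood-free
(0.05), and the panniculus matches the dermis bed (0.30) — its brightness in
scans comes from the deep vascular plexus, not the bed. Vessel voxels carry
total hemoglobin 2.0 at a configured oxygen saturation (default 0.70, a
mixed arterio-venous value).

**Vessels** are finite straight tubes (length 0.4–0.9 mm) of two diameter
classes — small (10–40 µm) and large (50–200 µm) — rasterized by
point-to-segment distance (a voxel belongs to a vessel if its center lies
within one radius of the centerline). Placement follows skin anatomy: the
dermis hosts a dense superficial plexus of small vessels (8 /mm²) in its
upper two thirds and a deep plexus of large vessels (3 /mm²) centered on the
dermis–hypodermis junction; dWAT is markedly vessel-poor (0.9 small +
0.3 large /mm² lean; 0.3 + 0.1 obese-sedentary); a subcutis band below dWAT
hosts the deep subcutaneous plexus (2.5 small + 1.5 large /mm²). The deep
plexuses are what the layer segmentation keys on, exactly as in real scans:
an early version with full-field straight vessels at random depths produced
projections with no dermis/dWAT contrast and was rejected as failing to
emulate the tissue.

Ground truth (layer thicknesses, per-layer vessel voxel counts and
densities, per-layer mean concentrations, dWAT share of skin) is computed
exactly from the voxel volumes. Generation is bit-reproducible from
(config, seed); every operation that consumes randomness builds its own
`numpy.random.Generator` from an explicit seed.

## MSOT forward model and unmixing

Per pixel and wavelength, the simulated signal is the linear mixture
Σ_c E(λ,c)·C_c plus i.i.d. Gaussian noise. Fluence is uniform across
wavelength and depth — deliberately matching the analysis, which fits raw
spectra with no fluence correction, so simulation and analysis share one
model and the round trip is exact at zero noise. Pixels are projections of
the concentration volumes: depth-averaged ("coronal", the default) or
slow-axis-averaged ("cross_section", rows = depth), the view used for
skin-layer analyses. The plane orientation is a modeling choice; the
cross-section is what the dWAT-percentage readout needs.

The chromophore library is synthetic: smooth closed forms with the
qualitative features of the real near-infrared spectra (Hb bump at 760 nm,
HbO₂ rising toward 900 nm, lipid peak at 930 nm, water rising toward 975 nm,
ICG peak at 800 nm). On the 27-wavelength grid its condition number is ≈ 7,
so five-component unmixing is well posed. Any spectra table (CSV with a
`wavelength_nm` column) can be substituted; off-grid tables are linearly
interpolated and a component that does not cover the grid is rejected by
name.

"Linear regression" is implemented as non-negative least squares
(`scipy.optimize.nnls` per pixel): coefficients are concentrations, and NNLS
prevents physically meaningless negative blood or lipid. An unconstrained
option (`nonnegative=False`) exists for comparison. Oxygen saturation is
reported only where TBV ≥ `tbv_floor` (default 1 % of the image's maximum
TBV) because sO₂ is ill-defined at zero blood signal; excluded pixels are
NaN and drop out of ROI means. ROI statistics are the mean over ROIs of the
per-ROI mean of defined pixels.

## RSOM forward model

For each raster position (the raster coincides with the phantom's lateral
grid; an acceptance radius in voxels can widen the column), the A-line
superposes bipolar Gaussian-derivative pulses, p(t) ∝ −t·exp(−t²/2σ²),
arriving at t = depth/c:

* **Vessels.** Acoustic frequency encodes emitter size: a vessel of diameter
  d emits at f ≈ κ·c/d with κ = 1.2, so a 30 µm vessel emits ≈ 60 MHz and a
  100 µm vessel ≈ 18 MHz (σ = 1/2πf). Within one column a vessel crossing is
  a single coherent emitter: one pulse at the amplitude-weighted vessel
  depth, with amplitude equal to the column-integrated 532 nm absorption.
  (Summing per-voxel bipolar pulses inside a vessel instead lets adjacent
  pulses cancel and shifts the emitted spectrum low, breaking the size
  encoding the band separation relies on.)
* **Diffuse background.** Non-vessel absorbing voxels emit per voxel at an
  effective background frequency (default 30 MHz) representing the
  unresolved capillary bed; the ±50 % texture prevents the bulk cancellation
  a uniform slab would show, while leaving the coherent edge signal that
  real interfaces produce (the "boundary echo" the segmentation refinement
  exploits).
* **Fluence.** Amplitudes decay as exp(−µ_eff·depth below the skin surface)
  with µ_eff = 2 mm⁻¹, a typical effective attenuation for green (532 nm)
  light in skin. Without it, deep interfaces (panniculus bottom) are
  unrealistically strong and capture the layer segmentation.
* 532 nm absorption coefficients: Hb and HbO₂ 1.0 each (near-isosbestic),
  lipid 0.001, water 0.0001, ICG 0.1 — blood dominates, fat is dark.
* Gaussian noise (default SD 0.02 in amplitude units, i.e. 1 % of the
  vessel blood concentration) is added per sample, seeded.

There is no lateral diffraction, focal-zone, acoustic-attenuation or
speckle-from-scattering model; a synthetic-aperture delay-and-sum
reconstruction is left as an extension point. The guard `fs ≥ 2·f_max`
rejects configurations whose pulses would alias (default sampling
250 MS/s, axial sample spacing c/fs = 6 µm).

## Band separation and reconstruction

Band-pass filtering is a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`): zero phase, so envelope peaks do not move (verified to
< 1 sample), with band edges as −3 dB points; the same filter is applied to
every dataset. Defaults: 10–40 MHz (low) and 40–120 MHz (high); the 40 MHz
edge belongs to both transition bands. Envelope reconstruction is the
analytic-signal magnitude per A-line mapped to depth; intensity stays linear
(no log compression) because the 20 % vessel threshold is defined on linear
intensity. Red/green composites (low/high band maximum-intensity
projections, per-channel min–max rescaled) are for visualization only.

**Which band feeds segmentation.** The layer boundaries are segmented on the
full-bandwidth envelope volume, not the 10–40 MHz band: a 10 MHz band edge
gives the band-limited envelope a one-sided tail of roughly c/10 MHz
≈ 100 µm below every layer edge, which biases any boundary estimator by
several voxels, while the full-band pulse (σ·c ≈ 8 µm at 30 MHz) keeps the
axial point-spread compact. The segmentation functions accept any band, so
the narrow-band variant remains one argument away. Density quantification
uses the full-band volume by default, with per-band densities also reported.

## Surface detection and flattening

The volume is first speckle-averaged laterally (5 × 5 uniform filter — the
surface is laterally smooth, per-column speckle is not). Per column, the
noise floor is the median absolute intensity of the top 10 % of depth
samples after a trailing running mean (window 3); detection is the first
depth exceeding `k_noise` (default 6) times the floor for 3 consecutive
samples, refined to the half-rise of the local surface peak — the half-rise
of a symmetric pulse sits at the true interface, cancelling the early bias
of a low threshold crossing. Columns with no detection are filled by 2-D
median filtering; if most columns have none the error "no surface found" is
raised. The detected map is median-filtered (5 × 5) and low-pass regularized
(Gaussian σ = 5 columns, matching the ~mm relief scale of skin); without
this, per-column jitter smears every stack MIP downward, because a maximum
projection extends the bright region by the worst column's error.
Flattening shifts each A-line up by its integer surface index (zero-fill at
the bottom, voxel count preserved); intensities are never interpolated, so
the later relative threshold sees unaltered values.

## Layer segmentation

Per 0.5 mm stack MIP, the boundary is the exact minimal-cost column-monotone
path (dynamic programming, slope limit ±2 voxels/column; ties break toward
the smaller row, so a featureless image yields the flattest, shallowest
admissible path). The node cost is `1 − normalized vertical gradient +
0.01 + depth penalty` computed on the MIP after: saturation at 3× the median
positive intensity (so single bright vessels cannot dominate the laterally
coherent layer edge), lateral uniform smoothing (9 columns) and axial
Gaussian smoothing (σ = 2 samples). The monotone depth penalty encodes that
the sought boundary is the *first* strong transition below the window start
— the dermis hangs from the surface, and deeper layers (panniculus) produce
their own, often stronger, edges. It is 0.4 per mm for the dermis bottom
(strong competitors below) and 0.05 per mm for the dWAT bottom (the rise
onto the subcutaneous plexus is the dominant transition in its window, so
only a tie-break is needed); both are far too small to move the path within
a single transition. Default search windows: 0.1–0.8 mm below the surface
(dermis bottom) and, in the pipeline, dermis bottom + 0.05 to + 1.2 mm
(dWAT bottom).

The DP path localizes the middle of the envelope fall, which sits below the
physical interface by about half the pulse width, and a stack where a dWAT
vessel hugs the dermis bottom can mislead it entirely. Two refinements fix
this:

1. **Global anchor.** After flattening the boundary is laterally
   near-constant, so its marker accumulates at a single row of the
   whole-volume mean depth profile while vessels at random depths spread
   out. The anchor is the shallowest row whose profile response (intensity
   minus the mean of a 25-sample window starting 3 samples below, sign
   flipped for dark-to-bright) reaches 60 % of the window maximum.
2. **Per-column sub-voxel refinement** on each stack's mean (not maximum)
   projection, within ±12 samples of the anchor and clamped to the search
   window: for the dermis bottom, the parabolic-interpolated local intensity
   peak — the deep-plexus line plus the boundary echo peaks exactly at the
   interface; for the dWAT bottom, the interpolated half-rise onto the
   subcutaneous plexus. Both markers use the same half-edge convention as
   surface detection, so pulse-width offsets cancel in thickness
   differences.

Dermis thickness is the mean over stacks of the column-mean boundary depth
(the dermis top is the flattened surface: the epidermis is below resolution
at 50 MHz). The dWAT analysis window spans the dermis bottom to bottom +
1 mm (clipped at the volume bottom with a warning) and is disjoint from the
dermis mask by construction. The dermis mask starts 0.08 mm below the
surface — epidermis thickness plus the pulse main lobe plus the
surface-refinement offset — excluding the epidermal surface line, which is
not vasculature and would otherwise set the relative density threshold.

## Quantification

**Vessel density** is N × dV: N counts voxels strictly above
`threshold_fraction` (default 0.2) of the reference maximum inside the layer
mask; dV is the voxel volume. The reference maximum defaults to the maximum
within the analyzed layer (`reference_scope="layer"`), making dermis and
dWAT densities independently normalized; `"volume"` switches to the global
maximum. Scaling all intensities leaves N unchanged; an all-zero region
yields zero, and the pipeline reports zero (rather than failing) for a
measured layer that came out empty on degenerate input.

**dWAT percentage of skin** operates on a cross-sectional lipid-coefficient
map: per column inside the skin ROI (epidermis + dermis + dWAT), the dWAT
extent is the longest contiguous run of lipid pixels above
`lipid_threshold_fraction` (default 0.5) of the column maximum — the
lipid-rich dermal fat band; deeper subcutaneous fat is separated from it by
the low-lipid panniculus, which is what terminates the run. The percentage
is 100 × the column-mean of extent/skin-extent. The pipeline builds the ROI
automatically (first row with appreciable total signal down to the end of
the first supra-threshold lipid run), emulating the expert-drawn ROI.

**Group statistics** report mean ± SEM per group and compare two groups with
Student's t-test, more than two with one-way ANOVA followed by Tukey's HSD,
with significance stars at 0.05 / 0.01 / 0.001; groups of size one are
summarized but excluded from tests with a notice.

## Pipeline and reproducibility

`run_experiment` drives simulate → band split → reconstruct → flatten →
segment → quantify → unmix → summarize for every subject of every group.
The top-level seed expands through `numpy.random.SeedSequence([seed,
group_index, subject_index])` into per-subject, per-stage sub-seeds, so runs
are bit-reproducible and adding a subject or group never perturbs the
others; the manifest records every seed and parameter.

## Problem sizes used in tests and acceptance

The validation experiments run at a reduced acquisition geometry chosen to
keep the full battery at a few minutes on one CPU while preserving all
structural features (four 0.5 mm stacks where stack splitting matters,
vessel diameters resolvable at the coarser raster): 15 / 30 µm raster steps
over 2 × 1 mm (end-to-end groups, n = 5 per group) or 2 × 2 mm (20-phantom
thickness recovery), phantom voxels 10 × 15 × 30 µm, vessel diameters
30–40 µm (small) and 60–150 µm (large). The full 4 × 2 mm, 7.5 / 15 µm
geometry is the package default for real-scale simulations.

## Known limitations

* The chromophore library is synthetic; absolute coefficient values are
  arbitrary units and only relative comparisons are meaningful (as in the
  emulated workflow).
* The RSOM forward model is per-column: no lateral diffraction, focal zone,
  acoustic attenuation/dispersion or scattering speckle. Passing tests show
  the analysis chain recovers what this model generates; they do not certify
  accuracy on hardware data, where reconstruction artifacts, motion and
  system noise add error sources the phantom does not emulate.
* Vessels are straight finite tubes; real microvasculature meanders and
  branches. Densities are therefore cleaner than real scans at equal counts.
* The dWAT-bottom boundary (used for the dWAT-thickness readout) relies on a
  visible subcutaneous plexus; in tissue with a silent subcutis it would
  need the fixed 1 mm window instead.
* MSOT fluence is uniform; in deep tissue, spectral coloring of the fluence
  biases unmixing in ways neither the simulator nor the analysis models.
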