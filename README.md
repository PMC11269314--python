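# oaskin

Quantitative analysis of optoacoustic (photoacoustic) skin imaging, built
around two complementary modalities and validated end-to-end on synthetic
layered-skin phantoms with known ground truth:

* **Multispectral tomography (MSOT) arm** — spectral unmixing of
  multi-wavelength optoacoustic image stacks (700–960 nm in 10 nm steps, 27
  wavelengths) into tissue chromophores (lipid, HbO₂, Hb, H₂O, ICG), with
  derived readouts for lipid content, total blood volume and tissue oxygen
  saturation, and the dermal-fat share of the skin.
* **Raster-scan mesoscopy (RSOM) arm** — frequency-band separation of
  single-wavelength (532 nm) A-line scans recorded by a 50 MHz focused
  transducer over a 4 × 2 mm² field (7.5 / 15 µm steps), envelope
  reconstruction, skin-surface flattening, dynamic-programming skin-layer
  segmentation, and voxel-count vessel-density quantification.

The intended users are researchers quantifying dermal white adipose tissue
(dWAT) and skin microvasculature in small-animal studies of obesity and
exercise intervention — and anyone who needs a tested, reusable
implementation of these readout chains with a phantom simulator to validate
against.

## The models

**Spectral unmixing.** Each pixel's measured spectrum is a non-negative
mixture of known chromophore absorption spectra E(λ, c):

```
C(pixel, ·) = argmin_{c ≥ 0} ‖ S(pixel, ·) − E c ‖₂        (NNLS)
```

Coefficients are concentrations in arbitrary units; no fluence correction is
applied (the fit is on raw spectra). Derived maps: total blood volume
TBV = C(Hb) + C(HbO₂) and oxygen saturation sO₂ = C(HbO₂)/(C(Hb)+C(HbO₂)),
the latter defined only where TBV exceeds a floor (default 1 % of the image
maximum). ROI statistics average the per-ROI means (three ROIs per subject by
convention).

**Band separation.** Acoustic emission frequency is inversely related to
emitter size, so each A-line is split with zero-phase Butterworth band-passes
into a low band (10–40 MHz, larger vessels, 50 to >100 µm, red channel) and a
high band (40–120 MHz, smaller vessels, 10–40 µm, green channel). Envelope
detection (analytic-signal magnitude) and depth mapping z = c·(t − t₀) yield
non-negative intensity volumes.

**Layer segmentation.** After surface detection and integer-voxel
flattening, the volume is split into 0.5 mm slow-axis stacks (four for the
2 mm field). The dermis bottom is traced on each stack's maximum-intensity
projection as an exact minimal-cost column-monotone path (dynamic
programming) on a gradient-derived cost image — the dermis is vessel-rich,
the dermal fat below it vessel-poor — then refined per column to sub-voxel
precision on the stack's mean projection. Dermis thickness is the average
boundary depth over the four stacks; the dWAT analysis window extends a
fixed 1 mm below the dermis bottom.

**Vessel density.** N × dV, where N counts voxels above 20 % of the
reference maximum intensity inside the analyzed layer mask and dV is the
voxel volume (mm³).

## Worked example

Simulate a lean-mouse phantom, run both arms, and compare against the
phantom's ground truth:

```python
import numpy as np
from oaskin import (
    ScanConfig, chow_like_config, make_phantom, simulate_rsom, simulate_msot,
    bandpass_split, envelope_reconstruct, detect_surface, flatten,
    dermis_thickness, dwat_window, vessel_density, unmix,
    oxygen_saturation, MSOT_GRID, default_library,
)
from oaskin.segmentation import layer_boundaries_from_volume, dermis_mask

config = chow_like_config(
    fast_extent_mm=2.0, slow_extent_mm=1.0,
    voxel_size_mm=(0.01, 0.015, 0.03), depth_mm=2.5,
    diameter_ranges_um={"small": (30.0, 40.0), "large": (60.0, 150.0)},
)
phantom = make_phantom(config, seed=11)

scan = simulate_rsom(phantom, ScanConfig(), seed=12)
low, high = bandpass_split(scan)                       # 10-40 / 40-120 MHz
volume = envelope_reconstruct(scan)
flat = flatten(volume, detect_surface(volume))

boundaries = layer_boundaries_from_volume(flat, stack_thickness_mm=0.5)
thickness = dermis_thickness(boundaries)
print(f"dermis thickness: measured {thickness:.3f} mm, "
      f"true {config.epidermis_thickness_mm + config.dermis_thickness_mm:.3f} mm")

for mask in (dermis_mask(boundaries, flat),
             dwat_window(boundaries, extension_mm=1.0, volume=flat)):
    res = vessel_density(flat, mask)
    print(f"{mask.layer_name} vessel density: N={res.N}, "
          f"N x dV = {res.density_mm3:.4f} mm^3")

library = default_library()
image = simulate_msot(phantom, MSOT_GRID, library,
                      noise_sd=0.0, seed=13, plane="cross_section")
so2 = oxygen_saturation(unmix(image, library))
print(f"mean sO2 in blood-bearing pixels: {np.nanmean(so2):.3f} "
      f"(generated: {config.so2})")
```

Output:

```
dermis thickness: measured 0.390 mm, true 0.380 mm
dermis vessel density: N=3551, N x dV = 0.0096 mm^3
dwat vessel density: N=6745, N x dV = 0.0182 mm^3
mean sO2 in blood-bearing pixels: 0.691 (generated: 0.7)
```

The measured dermis thickness recovers the generated one to one axial voxel;
the dermis (dense plexus) carries roughly half the vascular voxel volume of
the 1 mm dWAT window in this lean phantom, whose window also spans the deep
subcutaneous plexus; and the unmixed oxygen saturation reproduces the
generated 70 %.

The same workflow is available from the shell:

```
oaskin simulate --config run.yaml --seed 11 --out sim/
oaskin recon    --input sim/rsom.h5 --out recon/
oaskin segment  --input recon/band_full.h5 --out seg/
oaskin quantify --volume seg/flattened.h5 --masks seg/masks.h5 --out quant/
oaskin run      --config run.yaml --out report/     # full two-group study
```

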