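"""Forward models: multispectral stacks and raster scans from a phantom.

MSOT arm — per-pixel signal at wavelength λ is the linear mixture
Σ_c E(λ,c)·C_c(pixel) plus Gaussian noise; pixels are a projection of the
phantom's concentration volumes (depth-averaged "coronal" slab by default, or
a slow-axis-averaged cross-section showing the layer stratigraphy).  Fluence
is uniform across wavelength and depth, matching the raw-spectrum linear
regression the unmixing applies.

RSOM arm — for each raster position, the A-line is the superposition over
absorbing voxels in that acceptance column of a bipolar Gaussian-derivative
pulse arriving at t = depth/c.  The pulse's characteristic frequency encodes
emitter size, f ≈ κ·c/d for a vessel of diameter d (default κ = 1.2, so a
30 µm vessel emits ≈ 60 MHz and a 100 µm vessel ≈ 18 MHz); unresolved diffuse
tissue (capillary bed, epidermis) emits at a configurable effective background
frequency.  Pulse amplitude is proportional to the voxel's absorption at the
532 nm excitation wavelength, where hemoglobin dominates and lipid is nearly
transparent.  No lateral diffraction, attenuation or focal-zone model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal

from .phantom import Phantom
from .rsom import RsomScan
from .spectra import ChromophoreLibrary, WavelengthGrid
from .unmixing import MultispectralImage


def _default_absorption_532() -> dict:
    # relative absorption at 532 nm (a.u. per concentration unit); the two
    # hemoglobin forms are near-isosbestic there, lipid/water are negligible
    return {"Hb": 1.0, "HbO2": 1.0, "lipid": 0.001, "H2O": 0.0001, "ICG": 0.1}


@dataclass
class ScanConfig:
    """Acquisition parameters of the simulated raster scan."""

    fs_MHz: float = 250.0
    c_mm_per_us: float = 1.5
    noise_sd: float = 0.02
    kappa: float = 1.2  # f[MHz] = kappa * c[µm/µs] / d[µm]
    background_frequency_MHz: float = 30.0
    #: effective optical attenuation of the 532 nm excitation below the skin
    #: surface (1/mm); green light penetrates well under a millimeter in
    #: skin, so deep emitters are progressively dimmer
    fluence_mu_eff_per_mm: float = 2.0
    absorption_532: dict = field(default_factory=_default_absorption_532)
    acceptance_radius_voxels: int = 0
    t0_us: float = 0.0
    pad_samples: int = 64


def simulate_msot(
    phantom: Phantom,
    grid: WavelengthGrid,
    library: ChromophoreLibrary,
    noise_sd: float,
    seed: int,
    plane: str = "coronal",
) -> MultispectralImage:
    """Simulate a multispectral optoacoustic image of the phantom.

    ``plane="coronal"`` depth-averages the concentration volumes (en-face
    image, rows = fast axis, cols = slow axis); ``plane="cross_section"``
    averages over the slow axis (rows = depth, cols = fast axis), the view in
    which the skin layer stack is visible.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lib_wl = library.grid.values_nm
    rows = []
    for wl in grid.values_nm:
        match = np.nonzero(np.isclose(lib_wl, wl))[0]
        if match.size == 0:
            raise ValueError(f"wavelength {wl:g} nm missing from library")
        rows.append(int(match[0]))
    E = library.E[rows, :]  # (n_wl, n_comp)

    dz, dx, dy = phantom.voxel_size_mm
    if plane == "coronal":
        axis, pixel_size = 0, (dx, dy)
    elif plane == "cross_section":
        axis, pixel_size = 2, (dz, dx)
    else:
        raise ValueError(f"unknown plane {plane!r}")
    maps = []
    for comp in library.component_names:
        vol = phantom.concentration_volumes.get(comp)
        if vol is None:
            maps.append(None)
        else:
            maps.append(np.asarray(vol, dtype=float).mean(axis=axis))
    shape2d = next(m.shape for m in maps if m is not None)
    stack = np.stack(
        [m if m is not None else np.zeros(shape2d) for m in maps], axis=0
    )  # (n_comp, rows, cols)
    S = np.einsum("wk,krc->rcw", E, stack)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0.0, noise_sd, S.shape)
    return MultispectralImage(S=S, pixel_size_mm=pixel_size, grid=grid)


def gaussian_derivative_pulse(f_MHz: float, fs_MHz: float) -> np.ndarray:
    """Bipolar pulse whose amplitude spectrum peaks at ``f_MHz``.

    p(t) = -(t/σ)·exp(-t²/2σ²) with σ = 1/(2π f); scaled to unit peak.
    """
    sigma_us = 1.0 / (2.0 * np.pi * f_MHz)
    dt = 1.0 / fs_MHz
    half = max(int(np.ceil(4.0 * sigma_us / dt)), 2)
    t = np.arange(-half, half + 1) * dt
    return -(t / sigma_us) * np.exp(0.5 - t**2 / (2.0 * sigma_us**2))


def vessel_frequency_MHz(diameter_um: float, config: ScanConfig) -> float:
    """Characteristic emission frequency of a vessel of given diameter."""
    c_um_per_us = config.c_mm_per_us * 1000.0
    return config.kappa * c_um_per_us / diameter_um


def simulate_rsom(phantom: Phantom, scan: ScanConfig, seed: int) -> RsomScan:
    """Simulate a single-wavelength (532 nm) raster scan of the phantom.

    The raster coincides with the phantom's lateral voxel grid.  Emitters are
    grouped by characteristic frequency (one class per vessel, one diffuse
    background class); each class's depth-projected amplitude profile is
    convolved with its pulse kernel along the time axis and the classes are
    superposed, then Gaussian noise is added.  Same seed, same scan.
    """
    freqs = [scan.background_frequency_MHz] + [
        vessel_frequency_MHz(v.diameter_um, scan) for v in phantom.vessels
    ]
    f_max = max(freqs)
    if scan.fs_MHz < 2.0 * f_max:
        raise ValueError(
            f"sampling rate {scan.fs_MHz:g} MHz below twice the highest "
            f"configured pulse frequency ({f_max:g} MHz); aliasing"
        )

    dz, dx, dy = phantom.voxel_size_mm
    nz, nx, ny = phantom.shape
    dt = 1.0 / scan.fs_MHz
    depth_mm = nz * dz
    n_t = int(np.ceil(depth_mm / (scan.c_mm_per_us * dt))) + scan.pad_samples
    # fractional time-bin coordinate of each axial voxel center; amplitude is
    # deposited into the two nearest bins by linear interpolation so that the
    # phantom and acquisition depth grids need not be commensurate
    t_frac = (phantom.depth_coords_mm / scan.c_mm_per_us - scan.t0_us) / dt
    t_lo = np.clip(np.floor(t_frac).astype(int), 0, n_t - 1)
    t_hi = np.clip(t_lo + 1, 0, n_t - 1)
    w_hi = np.clip(t_frac - t_lo, 0.0, 1.0)
    w_lo = 1.0 - w_hi

    A = phantom.absorption_at(scan.absorption_532)
    if scan.fluence_mu_eff_per_mm > 0:
        surface = phantom.layer_boundaries_mm.get("surface")
        if surface is not None:
            depth_below = (
                phantom.depth_coords_mm[:, None, None] - surface[None, :, :]
            )
            A = A * np.exp(
                -scan.fluence_mu_eff_per_mm * np.maximum(depth_below, 0.0)
            )
    vessel_id = phantom.vessel_id_volume
    alines = np.zeros((n_t, nx, ny))

    def add_class(amplitude: np.ndarray, f_MHz: float, sl=(slice(None), slice(None))):
        T = np.zeros((n_t,) + amplitude.shape[1:])
        shape = (-1,) + (1,) * (amplitude.ndim - 1)
        np.add.at(T, t_lo, amplitude * w_lo.reshape(shape))
        np.add.at(T, t_hi, amplitude * w_hi.reshape(shape))
        if scan.acceptance_radius_voxels > 0:
            w = 2 * scan.acceptance_radius_voxels + 1
            T = scipy.ndimage.uniform_filter(T, size=(1, w, w)) * (w * w)
        kernel = gaussian_derivative_pulse(f_MHz, scan.fs_MHz)
        out = scipy.signal.fftconvolve(
            T, kernel[:, None, None], mode="same", axes=0
        )
        alines[:, sl[0], sl[1]] += out

    # diffuse background emitters
    bg = np.where(vessel_id < 0, A, 0.0)
    if np.any(bg > 0):
        add_class(bg, scan.background_frequency_MHz)

    # vessel emitters: within one column, a vessel crossing is a single
    # coherent emitter (per-voxel bipolar pulses would partially cancel and
    # shift the spectrum low) — one pulse per column at the amplitude-weighted
    # vessel depth, with the diameter-encoded characteristic frequency;
    # vessels are grouped by (rounded) frequency and processed within each
    # group's lateral bounding box
    if phantom.vessels:
        zc = phantom.depth_coords_mm
        f_of_vessel = np.array(
            [vessel_frequency_MHz(v.diameter_um, scan) for v in phantom.vessels]
        )
        f_key = np.round(f_of_vessel, 1)
        for f in np.unique(f_key):
            ids = np.nonzero(f_key == f)[0]
            mask = np.isin(vessel_id, ids)
            if not mask.any():
                continue
            xs = np.nonzero(mask.any(axis=(0, 2)))[0]
            ys = np.nonzero(mask.any(axis=(0, 1)))[0]
            r = scan.acceptance_radius_voxels
            sx = slice(max(xs[0] - r, 0), min(xs[-1] + r, nx - 1) + 1)
            sy = slice(max(ys[0] - r, 0), min(ys[-1] + r, ny - 1) + 1)
            amp = np.where(mask, A, 0.0)[:, sx, sy]
            weight = amp.sum(axis=0)
            hit = weight > 0
            if not hit.any():
                continue
            z_mean = np.zeros_like(weight)
            z_mean[hit] = (
                (amp * zc[:, None, None]).sum(axis=0)[hit] / weight[hit]
            )
            T = np.zeros((n_t,) + weight.shape)
            tf = (z_mean[hit] / scan.c_mm_per_us - scan.t0_us) / dt
            lo = np.clip(np.floor(tf).astype(int), 0, n_t - 1)
            hi = np.clip(lo + 1, 0, n_t - 1)
            wh = np.clip(tf - lo, 0.0, 1.0)
            ix, iy = np.nonzero(hit)
            np.add.at(T, (lo, ix, iy), weight[hit] * (1.0 - wh))
            np.add.at(T, (hi, ix, iy), weight[hit] * wh)
            if scan.acceptance_radius_voxels > 0:
                w = 2 * scan.acceptance_radius_voxels + 1
                T = scipy.ndimage.uniform_filter(T, size=(1, w, w)) * (w * w)
            kernel = gaussian_derivative_pulse(float(f), scan.fs_MHz)
            alines[:, sx, sy] += scipy.signal.fftconvolve(
                T, kernel[:, None, None], mode="same", axes=0
            )

    if scan.noise_sd > 0:
        rng = np.random.default_rng(seed)
        alines += rng.normal(0.0, scan.noise_sd, alines.shape)

    return RsomScan(
        alines=alines,
        fs_MHz=scan.fs_MHz,
        c_mm_per_us=scan.c_mm_per_us,
        dx_mm=dx,
        dy_mm=dy,
        t0_us=scan.t0_us,
        center_frequency_MHz=50.0,
    )
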