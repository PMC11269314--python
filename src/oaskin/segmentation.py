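"""Skin surface detection, flattening and layer segmentation.

The workflow mirrors standard mesoscopic skin analysis: detect the skin
surface in the unflattened envelope volume, shift every A-line so the surface
sits at depth 0 (integer-voxel shifts, leaving intensity values untouched for
the later relative threshold), split the volume into slow-axis stacks of fixed
thickness (0.5 mm by default, four stacks for the 2 mm field), take the
maximum-intensity projection (MIP) of each stack, and trace the dermis bottom
in each MIP as a column-monotone minimal-cost path — a shortest path on a
gradient-derived cost image with a hard slope constraint, solved exactly by
dynamic programming.  The dermis is vessel-rich and the dermal fat (dWAT)
below it vessel-poor, so the dermis bottom is a bright-to-dark transition; the
dWAT bottom, where the deep vascular plexus resumes, is the opposite polarity.
Dermis thickness is the average over stacks and columns of the segmented
boundary depth below the flattened surface (the dermis top coincides with the
surface: the epidermis is below resolution at 50 MHz).  The dWAT analysis
window extends a fixed 1 mm below the dermis bottom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .rsom import BandVolume


@dataclass
class SurfaceMap:
    """Detected skin surface: one depth index per lateral position."""

    indices: np.ndarray  # (n_fast, n_slow) int
    detection_threshold: float


@dataclass
class LayerBoundaries:
    """Per-stack boundary depth (mm below the flattened surface) per column."""

    boundaries_mm: np.ndarray  # (n_stacks, n_fast)
    dz_mm: float
    stack_slow_indices: list  # list of index arrays into the slow axis

    @property
    def n_stacks(self) -> int:
        return self.boundaries_mm.shape[0]


@dataclass
class LayerMask:
    """Boolean volume selecting one layer."""

    mask: np.ndarray  # (depth, fast, slow) bool
    layer_name: str


def _trailing_mean(v: np.ndarray, window: int) -> np.ndarray:
    """Running mean over the trailing ``window`` samples along axis 0."""
    c = np.cumsum(v, axis=0, dtype=float)
    out = np.empty_like(c)
    out[:window] = c[:window] / np.arange(1, window + 1).reshape(
        (-1,) + (1,) * (v.ndim - 1)
    )
    out[window:] = (c[window:] - c[:-window]) / window
    return out


def detect_surface(
    volume: BandVolume,
    k_noise: float = 6.0,
    smooth_window: int = 3,
    air_fraction: float = 0.1,
    min_run: int = 3,
    refine_window: int = 16,
    lateral_median: int = 5,
    lateral_presmooth: int = 5,
    smooth_sigma_lateral: float = 5.0,
) -> SurfaceMap:
    """Find the first supra-threshold depth per A-line.

    The noise floor is the median absolute intensity of the top air gap
    (the first ``air_fraction`` of depth samples) after trailing-mean
    smoothing; a column detects at the first depth where the smoothed A-line
    exceeds ``k_noise`` times the floor for ``min_run`` consecutive samples,
    then the detection is refined to the half-rise of the local surface peak
    (the half-rise of a symmetric pulse sits at the true interface, removing
    the early bias a low threshold crossing would have).  Columns without a
    detection are filled by 2-D median filtering of the detected map; if most
    columns have none, there is no surface to find.
    """
    if volume.flattened:
        raise ValueError("volume is already flattened")
    V = volume.V
    nz = V.shape[0]
    if lateral_presmooth and lateral_presmooth > 1 and V.shape[1] * V.shape[2] > 1:
        # average envelope speckle laterally before thresholding; the skin
        # surface is laterally smooth, per-column speckle is not
        V = scipy.ndimage.uniform_filter(
            V, size=(1, lateral_presmooth, lateral_presmooth)
        )
    sm = _trailing_mean(V, smooth_window)
    n_air = max(4, int(air_fraction * nz))
    floor = float(np.median(np.abs(sm[:n_air])))
    threshold = k_noise * floor
    above = sm > threshold
    run = above.copy()
    for k in range(1, min_run):
        run[: nz - k] &= above[k:]
        run[nz - k :] = False
    detected = run.any(axis=0)
    if detected.mean() < 0.5:
        raise ValueError("no surface found")
    idx = np.argmax(run, axis=0)

    # half-rise refinement within [idx, idx + refine_window]
    cols = np.nonzero(detected)
    for i, j in zip(*cols):
        z0 = idx[i, j]
        z1 = min(z0 + refine_window, nz)
        peak = sm[z0:z1, i, j].max()
        half = np.nonzero(sm[z0:z1, i, j] >= 0.5 * peak)[0]
        idx[i, j] = z0 + int(half[0])

    if not detected.all():
        filler = int(np.median(idx[detected]))
        tmp = np.where(detected, idx, filler)
        med = scipy.ndimage.median_filter(tmp, size=3)
        idx = np.where(detected, idx, med)
    if lateral_median and lateral_median > 1:
        # the physical skin surface is laterally smooth; median filtering
        # removes per-column detection jitter without rounding real relief
        idx = scipy.ndimage.median_filter(idx, size=lateral_median)
    if smooth_sigma_lateral and smooth_sigma_lateral > 0:
        # low-pass regularization at the ~mm relief scale of skin; residual
        # per-column jitter would otherwise smear every stack MIP downward
        idx = np.rint(
            scipy.ndimage.gaussian_filter(
                idx.astype(float), smooth_sigma_lateral
            )
        ).astype(int)
    return SurfaceMap(indices=idx.astype(int), detection_threshold=threshold)


def flatten(volume: BandVolume, surface: SurfaceMap) -> BandVolume:
    """Shift each A-line up by its surface index (integer shift, zero-fill).

    Voxel count is preserved; intensities are not interpolated.
    """
    if volume.flattened:
        raise ValueError("volume is already flattened")
    V = volume.V
    nz = V.shape[0]
    if surface.indices.shape != V.shape[1:]:
        raise ValueError("surface map does not match the volume's lateral grid")
    if surface.indices.min() < 0 or surface.indices.max() >= nz:
        raise ValueError("surface indices outside the volume depth range")
    src = np.arange(nz)[:, None, None] + surface.indices[None, :, :]
    valid = src < nz
    gathered = np.take_along_axis(V, np.minimum(src, nz - 1), axis=0)
    out = np.where(valid, gathered, 0.0)
    return BandVolume(
        V=out,
        band_MHz=volume.band_MHz,
        voxel_size_mm=volume.voxel_size_mm,
        flattened=True,
    )


def _stack_index_groups(n_slow: int, n_stacks: int) -> list:
    return np.array_split(np.arange(n_slow), n_stacks)


def split_stacks(volume: BandVolume, stack_thickness_mm: float = 0.5) -> list:
    """Split a flattened volume into contiguous slow-axis stacks.

    The stack count is ``round(slow_extent / stack_thickness)``; the default
    geometry (2 mm slow extent, 0.5 mm stacks) yields four stacks.
    """
    if not volume.flattened:
        raise ValueError("volume must be flattened before stacking")
    dy = volume.voxel_size_mm[2]
    n_slow = volume.V.shape[2]
    extent = n_slow * dy
    n_stacks = int(round(extent / stack_thickness_mm))
    if n_stacks < 1:
        raise ValueError("stack thickness exceeds the slow-axis extent")
    if abs(extent - n_stacks * stack_thickness_mm) > stack_thickness_mm:
        raise ValueError(
            f"slow extent {extent:g} mm is not a whole number of "
            f"{stack_thickness_mm:g} mm stacks"
        )
    groups = _stack_index_groups(n_slow, n_stacks)
    if min(len(g) for g in groups) < 3:
        raise ValueError("stacks thinner than 3 slow-axis steps")
    return [
        BandVolume(
            V=volume.V[:, :, g],
            band_MHz=volume.band_MHz,
            voxel_size_mm=volume.voxel_size_mm,
            flattened=True,
        )
        for g in groups
    ]


def stack_mip(stack: BandVolume) -> np.ndarray:
    """Maximum-intensity projection over the slow axis: (depth, fast) image."""
    return stack.V.max(axis=2)


def dp_shortest_path(cost: np.ndarray, max_slope: int) -> np.ndarray:
    """Exact minimal-cost left-to-right path through a (rows, cols) cost image.

    Consecutive columns may change row by at most ``max_slope``.  Ties are
    broken toward the smaller row at every choice, so a uniform cost image
    yields the flattest admissible path along the top row.  Returns one row
    index per column.
    """
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0:
        raise ValueError("empty cost image")
    offsets = np.arange(-max_slope, max_slope + 1)
    dp = cost[:, 0].astype(float).copy()
    back = np.zeros((n_cols, n_rows), dtype=int)
    rows = np.arange(n_rows)
    for col in range(1, n_cols):
        # candidate predecessor rows, ordered ascending so argmin tie-breaks
        # toward the smaller row
        cand = np.full((offsets.size, n_rows), np.inf)
        for k, off in enumerate(offsets):
            prev = rows + off
            ok = (prev >= 0) & (prev < n_rows)
            cand[k, ok] = dp[prev[ok]]
        best = np.argmin(cand, axis=0)
        dp = cand[best, rows] + cost[:, col]
        back[col] = np.clip(rows + offsets[best], 0, n_rows - 1)
    path = np.empty(n_cols, dtype=int)
    path[-1] = int(np.argmin(dp))
    for col in range(n_cols - 1, 0, -1):
        path[col - 1] = back[col, path[col]]
    return path


def _boundary_cost(
    mip: np.ndarray,
    polarity: str,
    smooth_sigma: float,
    lateral_smooth: int = 9,
    saturate_k: float = 3.0,
) -> np.ndarray:
    # saturate the intensity scale (at a multiple of the median, i.e. of the
    # diffuse background level) so that single bright vessels do not dominate
    # the laterally coherent layer transition, then smooth along both axes
    # before taking the vertical gradient
    sm = np.asarray(mip, dtype=float)
    if saturate_k is not None and np.any(sm > 0):
        sm = np.minimum(sm, saturate_k * np.median(sm[sm > 0]))
    if lateral_smooth and lateral_smooth > 1:
        sm = scipy.ndimage.uniform_filter1d(sm, lateral_smooth, axis=1)
    sm = scipy.ndimage.gaussian_filter1d(sm, smooth_sigma, axis=0)
    grad = sm[:-1, :] - sm[1:, :]  # positive where bright above, dark below
    if polarity == "dark_to_bright":
        grad = -grad
    elif polarity != "bright_to_dark":
        raise ValueError(f"unknown polarity {polarity!r}")
    lo, hi = float(grad.min()), float(grad.max())
    norm = (grad - lo) / (hi - lo) if hi > lo else np.zeros_like(grad)
    return 1.0 - norm + 0.01


def segment_boundary(
    mip: np.ndarray,
    dz_mm: float,
    search_window_mm: tuple,
    max_slope: int = 2,
    polarity: str = "bright_to_dark",
    smooth_sigma: float = 2.0,
    depth_penalty_per_mm: float = 0.4,
) -> np.ndarray:
    """Trace a layer boundary across a flattened stack MIP.

    Node cost is ``1 - normalized vertical gradient`` (of the requested
    polarity) plus a small constant plus a gentle monotone depth penalty —
    the sought boundary is the *first* strong transition below the window
    start (the dermis hangs from the surface; deeper layers produce their own
    transitions), and the penalty is far too small to move the path within a
    single transition.  The minimal-cost column-monotone path is found by
    :func:`dp_shortest_path`.  Returns the boundary depth in mm below the
    flattened surface per fast-axis column: a path row ``r`` marks the
    transition between voxel rows ``r`` and ``r+1``, i.e. depth ``(r+1)*dz``.
    """
    lo_mm, hi_mm = search_window_mm
    n_grad = mip.shape[0] - 1
    i0 = max(int(round(lo_mm / dz_mm)), 0)
    i1 = min(int(round(hi_mm / dz_mm)), n_grad)
    if i1 <= i0:
        raise ValueError(
            f"empty search window [{lo_mm:g}, {hi_mm:g}] mm at dz={dz_mm:g}"
        )
    cost = _boundary_cost(mip, polarity, smooth_sigma)[i0:i1, :]
    cost = cost + depth_penalty_per_mm * dz_mm * np.arange(cost.shape[0])[:, None]
    path = dp_shortest_path(cost, max_slope)
    return (i0 + path + 1) * dz_mm


def segment_dermis_bottom(
    mip: np.ndarray,
    dz_mm: float,
    search_window_mm: tuple = (0.1, 0.8),
    max_slope: int = 2,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Dermis bottom: bright-to-dark transition into the vessel-poor dWAT."""
    return segment_boundary(
        mip, dz_mm, search_window_mm, max_slope, "bright_to_dark", smooth_sigma
    )


def segment_dwat_bottom(
    mip: np.ndarray,
    dz_mm: float,
    search_window_mm: tuple = (0.3, 1.8),
    max_slope: int = 2,
    smooth_sigma: float = 2.0,
    depth_penalty_per_mm: float = 0.05,
) -> np.ndarray:
    """dWAT bottom: dark-to-bright transition onto the deep vascular plexus.

    The rise onto the subcutaneous plexus is the dominant dark-to-bright
    transition in the window (attenuation leaves nothing brighter below), so
    only a minimal tie-break depth penalty is applied.
    """
    return segment_boundary(
        mip,
        dz_mm,
        search_window_mm,
        max_slope,
        "dark_to_bright",
        smooth_sigma,
        depth_penalty_per_mm,
    )


def refine_boundary_on_stack(
    stack: BandVolume,
    anchor_row: int,
    polarity: str = "bright_to_dark",
    search: int = 12,
    lateral_smooth: int = 9,
    bounds: tuple | None = None,
) -> np.ndarray:
    """Sub-voxel per-column boundary refinement on a stack's mean projection.

    The dynamic-programming path on the MIP is robust but localizes the
    middle of the envelope fall, which sits below the physical interface by
    about half the pulse envelope width.  The mean (not maximum) slow-axis
    projection is statistically symmetric about the interface, and carries an
    unbiased marker at each boundary type: the dermis bottom is the local
    intensity peak of the deep dermal plexus line plus the boundary echo
    (``bright_to_dark``: parabolic-interpolated local maximum near the
    anchor), while the dWAT bottom is the half-rise onto the subcutaneous
    plexus (``dark_to_bright``: interpolated crossing of the mid-level
    between the dark floor above and the bright plateau below).  Returns a
    float row index per fast-axis column.
    """
    mp = stack.V.mean(axis=2)
    if lateral_smooth and lateral_smooth > 1:
        mp = scipy.ndimage.uniform_filter1d(mp, lateral_smooth, axis=1)
    n, n_cols = mp.shape
    zlo = max(int(anchor_row) - search, 1)
    zhi = min(int(anchor_row) + search, n - 2)
    if bounds is not None:
        zlo = max(zlo, int(bounds[0]))
        zhi = min(zhi, int(bounds[1]))
        zhi = max(zhi, zlo)
    out = np.empty(n_cols)
    for c in range(n_cols):
        col = mp[:, c]
        if polarity == "bright_to_dark":
            z = zlo + int(np.argmax(col[zlo : zhi + 1]))
            # parabolic sub-voxel interpolation around the peak
            y0, y1, y2 = col[z - 1], col[z], col[z + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-300 else 0.0
            out[c] = z + float(np.clip(delta, -1.0, 1.0))
        elif polarity == "dark_to_bright":
            floor = col[max(zlo - search, 0) : zlo + 1].min()
            plateau = col[zhi : min(zhi + search, n)].max()
            half = 0.5 * (floor + plateau)
            cross = None
            for z in range(zlo, zhi + 1):
                if col[z] >= half > col[z - 1]:
                    frac = (half - col[z - 1]) / (col[z] - col[z - 1])
                    cross = z - 1 + frac
                    break
            out[c] = cross if cross is not None else anchor_row
        else:
            raise ValueError(f"unknown polarity {polarity!r}")
    return out


def _global_anchor_row(
    volume: BandVolume,
    window_rows: tuple,
    polarity: str,
    gap: int = 3,
    width: int = 25,
    prominence_fraction: float = 0.6,
) -> int | None:
    """Consensus boundary row from the whole-volume mean depth profile.

    After flattening, the sought boundary sits at one depth across the whole
    field, so its marker (deep-plexus/echo line over dark fat, or the rise
    onto the subcutaneous plexus) accumulates at a single row of the global
    profile while vessels at random depths spread out.  Returns the
    shallowest row whose response reaches ``prominence_fraction`` of the
    window maximum — the first strong transition — or None if the profile is
    featureless.
    """
    prof = volume.V.mean(axis=(1, 2))
    n = prof.shape[0]
    z0, z1 = max(window_rows[0], 1), min(window_rows[1], n - gap - 2)
    if z1 <= z0:
        return None
    z = np.arange(z0, z1)
    b0 = np.minimum(z + gap, n - 1)
    b1 = np.minimum(b0 + width, n)
    c = np.concatenate([[0.0], np.cumsum(prof)])
    below = (c[b1] - c[b0]) / np.maximum(b1 - b0, 1)
    if polarity == "bright_to_dark":
        resp = prof[z] - below
    else:
        a0 = np.maximum(z - width, 0)
        above = (c[z] - c[a0]) / np.maximum(z - a0, 1)
        resp = below - above
    r_max = resp.max()
    if not np.isfinite(r_max) or r_max <= 0:
        return None
    first = int(np.argmax(resp >= prominence_fraction * r_max))
    return int(z[first] + np.argmax(resp[first : first + gap + 1]))


def layer_boundaries_from_volume(
    volume: BandVolume,
    stack_thickness_mm: float = 0.5,
    which: str = "dermis_bottom",
    search_window_mm: tuple | None = None,
    max_slope: int = 2,
    smooth_sigma: float = 2.0,
    refine: bool = True,
    denoise_lateral: int = 0,
) -> LayerBoundaries:
    """Segment one boundary in every stack of a flattened volume.

    The volume is first speckle-averaged laterally (``denoise_lateral``),
    which keeps the noise-envelope floor of the stack MIPs from swallowing
    the attenuated contrast of deep layer transitions.  Per stack: dynamic
    programming on the MIP finds the boundary path, then (``refine=True``)
    :func:`refine_boundary_on_stack` relocalizes each column on the stack's
    mean projection around the global path median.
    """
    if denoise_lateral and denoise_lateral > 1:
        volume = BandVolume(
            V=np.maximum(
                scipy.ndimage.uniform_filter(
                    volume.V, size=(1, denoise_lateral, denoise_lateral)
                ),
                0.0,
            ),
            band_MHz=volume.band_MHz,
            voxel_size_mm=volume.voxel_size_mm,
            flattened=volume.flattened,
        )
    stacks = split_stacks(volume, stack_thickness_mm)
    groups = _stack_index_groups(volume.V.shape[2], len(stacks))
    dz = volume.voxel_size_mm[0]
    seg_fns = {
        "dermis_bottom": (segment_dermis_bottom, (0.1, 0.8), "bright_to_dark"),
        "dwat_bottom": (segment_dwat_bottom, (0.3, 1.8), "dark_to_bright"),
    }
    try:
        fn, default_window, polarity = seg_fns[which]
    except KeyError:
        raise ValueError(f"unknown boundary {which!r}") from None
    window = search_window_mm if search_window_mm is not None else default_window
    paths = [fn(stack_mip(s), dz, window, max_slope, smooth_sigma) for s in stacks]
    rows = []
    if refine:
        # the flattened boundary is laterally near-constant, so a single
        # volume-wide anchor guards each stack's refinement against stacks
        # where a vessel masks the transition: prefer the consensus row of
        # the global depth profile, falling back to the median DP row
        window_rows = (
            int(round(window[0] / dz)),
            int(round(window[1] / dz)),
        )
        anchor = _global_anchor_row(volume, window_rows, polarity)
        if anchor is None:
            anchor = (
                int(np.median(np.concatenate([np.rint(b / dz) for b in paths])))
                - 1
            )
        anchor = int(np.clip(anchor, window_rows[0], window_rows[1]))
        for s in stacks:
            rows.append(
                refine_boundary_on_stack(
                    s, anchor, polarity, bounds=window_rows
                )
                * dz
            )
    else:
        rows = paths
    return LayerBoundaries(
        boundaries_mm=np.stack(rows, axis=0),
        dz_mm=dz,
        stack_slow_indices=list(groups),
    )


def dermis_thickness(boundaries: LayerBoundaries) -> float:
    """Mean over stacks of the column-mean boundary depth (mm).

    With four stacks this is the average width of the four segmented
    boundaries; the dermis top is the flattened surface (depth 0).
    """
    if boundaries.n_stacks < 1:
        raise ValueError("no stack boundaries")
    return float(boundaries.boundaries_mm.mean(axis=1).mean())


def layer_thickness(
    top: LayerBoundaries, bottom: LayerBoundaries
) -> float:
    """Mean thickness between two segmented boundaries (e.g. dWAT)."""
    if top.boundaries_mm.shape != bottom.boundaries_mm.shape:
        raise ValueError("boundary sets have different shapes")
    return float(
        (bottom.boundaries_mm - top.boundaries_mm).mean(axis=1).mean()
    )


def _column_masks(
    boundaries: LayerBoundaries, volume: BandVolume
) -> tuple:
    """Per-voxel dermis-bottom index map on the full (fast, slow) grid."""
    nz, nx, ny = volume.V.shape
    b_idx = np.rint(boundaries.boundaries_mm / boundaries.dz_mm).astype(int)
    full = np.empty((nx, ny), dtype=int)
    for s, idx in enumerate(boundaries.stack_slow_indices):
        full[:, idx] = b_idx[s][:, None]
    return full, nz


def dermis_mask(
    boundaries: LayerBoundaries,
    volume: BandVolume,
    surface_standoff_mm: float = 0.08,
) -> LayerMask:
    """Voxels between the flattened surface and the dermis bottom.

    The standoff below the surface excludes the epidermal surface line
    (epidermis thickness plus the main lobe of the pulse envelope and the
    surface-detection offset), which is not vasculature and would otherwise
    dominate the relative intensity threshold of the vessel-density
    statistic.
    """
    full, nz = _column_masks(boundaries, volume)
    depth = np.arange(nz)[:, None, None]
    top = int(round(surface_standoff_mm / boundaries.dz_mm))
    mask = (depth >= top) & (depth < full[None, :, :])
    return LayerMask(mask=mask, layer_name="dermis")


def dwat_window(
    boundaries: LayerBoundaries,
    extension_mm: float = 1.0,
    volume: BandVolume | None = None,
) -> LayerMask:
    """The dWAT analysis window: dermis bottom to bottom + ``extension_mm``.

    Clipped at the volume depth (with a warning); disjoint from the dermis
    mask by construction.
    """
    if extension_mm <= 0:
        raise ValueError("extension_mm must be positive")
    if volume is None:
        raise ValueError("a flattened volume is required to shape the mask")
    if not volume.flattened:
        raise ValueError("volume must be flattened")
    full, nz = _column_masks(boundaries, volume)
    n_ext = int(round(extension_mm / boundaries.dz_mm))
    if (full + n_ext > nz).any():
        warnings.warn(
            "dWAT window extends past the volume bottom; clipped",
            stacklevel=2,
        )
    depth = np.arange(nz)[:, None, None]
    mask = (depth >= full[None, :, :]) & (depth < (full + n_ext)[None, :, :])
    return LayerMask(mask=mask, layer_name="dwat")
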