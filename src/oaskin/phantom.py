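"""Synthetic layered-skin phantoms with known ground truth.

A phantom is a voxelized block of mouse skin seen from above: a water/air
coupling gap, then epidermis, dermis, dermal white adipose tissue (dWAT), a
thin vascular panniculus band, and subcutaneous fat (scWAT) to the bottom of
the box.  Layer interfaces undulate conformally (all layers share one smooth
lateral undulation, so configured thicknesses are exact).  Tubular vessels of
two diameter classes are placed in the dermis, the dWAT and the subcutis;
vessel voxels carry oxy-/deoxy-hemoglobin at a configured oxygen saturation,
adipose layers carry elevated lipid.  Every quantity the analysis pipeline is
supposed to recover (layer thicknesses, vessel voxel counts and densities,
per-layer mean concentrations) is computable exactly from the phantom, which
makes it the oracle of all recovery tests.

Axes and units: depth is axis 0 (positive downward), fast scan axis is axis 1,
slow scan axis is axis 2; all geometry in mm.  Axial voxels are the half-open
intervals [k*dz, (k+1)*dz) with centers at (k+0.5)*dz; lateral grids are
sample points at k*dx (k = 0..floor(extent/dx)), matching a raster scan that
includes both field edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LAYER_NAMES = ("air", "epidermis", "dermis", "dwat", "panniculus", "scwat")

#: Admissible vessel diameter ranges (µm) per size class; the two classes are
#: the ones band separation is designed to distinguish.
SIZE_CLASS_RANGES_UM = {"small": (10.0, 40.0), "large": (50.0, 200.0)}


@dataclass(frozen=True)
class Vessel:
    """A straight tubular vessel segment."""

    centerline_mm: np.ndarray  # (n_points, 3) as (z, x, y)
    diameter_um: float
    size_class: str  # "small" | "large"

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASS_RANGES_UM:
            raise ValueError(f"unknown size class {self.size_class!r}")
        lo, hi = SIZE_CLASS_RANGES_UM[self.size_class]
        if not (lo <= self.diameter_um <= hi):
            raise ValueError(
                f"{self.size_class} vessel diameter {self.diameter_um:g} µm "
                f"outside [{lo:g}, {hi:g}] µm"
            )


def _default_vessels_per_mm2() -> dict:
    # Lateral areal densities (vessel segments per mm^2 of scan field) per
    # (layer, size class).  The dermis carries a dense plexus that nearly
    # saturates a stack MIP; dWAT is markedly vessel-poor and appears dark
    # with isolated streaks; the subcutis band below dWAT hosts the deep
    # plexus used to find the dWAT bottom.
    return {
        ("dermis", "small"): 8.0,
        ("dermis", "large"): 3.0,
        ("dwat", "small"): 0.9,
        ("dwat", "large"): 0.3,
        ("subcutis", "small"): 2.5,
        ("subcutis", "large"): 1.5,
    }


def _default_baselines() -> dict:
    # Diffuse chromophore baselines (arbitrary concentration units) per layer.
    # The epidermis baseline provides the surface line every raster scan of
    # skin shows; the panniculus is blood-rich (muscle + deep plexus); adipose
    # layers are lipid-rich and blood-poor.
    return {
        "air": {},
        "epidermis": {"Hb": 0.12, "HbO2": 0.13, "H2O": 0.5},
        "dermis": {"Hb": 0.10, "HbO2": 0.20, "lipid": 0.10, "H2O": 0.60},
        "dwat": {"Hb": 0.015, "HbO2": 0.035, "lipid": 1.00, "H2O": 0.20},
        "panniculus": {"Hb": 0.10, "HbO2": 0.20, "lipid": 0.08, "H2O": 0.70},
        "scwat": {"Hb": 0.015, "HbO2": 0.035, "lipid": 0.90, "H2O": 0.20},
    }


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic experiment.

    Defaults reproduce the acquisition geometry of the emulated scanner
    (4 x 2 mm field, 7.5 / 15 µm raster steps) and a lean adult mouse skin;
    see :func:`chow_like_config` / :func:`hfd_sedentary_like_config` for the
    two experimental groups.
    """

    fast_extent_mm: float = 4.0
    slow_extent_mm: float = 2.0
    depth_mm: float = 3.0
    voxel_size_mm: tuple = (0.010, 0.0075, 0.015)  # (dz, dx, dy)
    air_gap_mm: float = 0.30
    epidermis_thickness_mm: float = 0.03
    dermis_thickness_mm: float = 0.35
    dwat_thickness_mm: float = 0.30
    panniculus_thickness_mm: float = 0.10
    undulation_amplitude_mm: float = 0.02
    undulation_period_mm: float = 1.5
    vessels_per_mm2: dict = field(default_factory=_default_vessels_per_mm2)
    diameter_ranges_um: dict = field(
        default_factory=lambda: {"small": (18.0, 40.0), "large": (50.0, 150.0)}
    )
    vessel_length_mm: tuple = (0.4, 0.9)
    blood_concentration: float = 2.0
    so2: float = 0.70
    baselines: dict = field(default_factory=_default_baselines)
    texture_amplitude: float = 0.5
    components: tuple = ("lipid", "HbO2", "Hb", "H2O", "ICG")

    def validate(self) -> None:
        dz, dx, dy = self.voxel_size_mm
        if min(dz, dx, dy) <= 0:
            raise ValueError("voxel sizes must be positive")
        stack = (
            self.air_gap_mm
            + self.epidermis_thickness_mm
            + self.dermis_thickness_mm
            + self.dwat_thickness_mm
            + self.panniculus_thickness_mm
        )
        if stack + self.undulation_amplitude_mm >= self.depth_mm:
            raise ValueError(
                f"layer stack ({stack:g} mm + undulation) exceeds depth_mm "
                f"({self.depth_mm:g} mm)"
            )
        min_voxel_um = 1000.0 * max(self.voxel_size_mm)
        for cls, (lo, hi) in self.diameter_ranges_um.items():
            if any(
                self.vessels_per_mm2.get((layer, cls), 0) > 0
                for layer in ("dermis", "dwat", "subcutis")
            ) and lo < min_voxel_um:
                raise ValueError(
                    f"{cls} vessel diameter {lo:g} µm below largest voxel "
                    f"dimension {min_voxel_um:g} µm; unresolvable"
                )
            lo_cls, hi_cls = SIZE_CLASS_RANGES_UM[cls]
            if lo < lo_cls or hi > hi_cls:
                raise ValueError(
                    f"{cls} diameter range [{lo:g}, {hi:g}] outside class "
                    f"range [{lo_cls:g}, {hi_cls:g}] µm"
                )


@dataclass
class GroundTruth:
    """Exact readouts derived from a phantom (the recovery-test oracle)."""

    dermis_thickness_mm: float
    dwat_thickness_mm: float
    vessel_voxel_count_by_layer: dict
    vessel_density_mm3_by_layer: dict
    mean_concentration_by_layer: dict
    dwat_skin_percentage: float


@dataclass
class Phantom:
    """Voxelized layered skin with vessels and chromophore concentrations."""

    config: PhantomConfig
    seed: int
    voxel_size_mm: tuple  # (dz, dx, dy)
    layer_boundaries_mm: dict  # name -> (nx, ny) depth map, positive downward
    vessels: list
    concentration_volumes: dict  # component -> (nz, nx, ny) float32
    layer_volume: np.ndarray  # (nz, nx, ny) uint8 labels into LAYER_NAMES
    vessel_id_volume: np.ndarray  # (nz, nx, ny) int32, -1 = no vessel

    @property
    def shape(self) -> tuple:
        return self.layer_volume.shape

    @property
    def depth_coords_mm(self) -> np.ndarray:
        dz = self.voxel_size_mm[0]
        return (np.arange(self.shape[0]) + 0.5) * dz

    def absorption_at(self, coefficients: dict) -> np.ndarray:
        """Total absorption volume for per-component absorption coefficients."""
        out = np.zeros(self.shape, dtype=np.float64)
        for name, eps in coefficients.items():
            if name in self.concentration_volumes and eps != 0.0:
                out += eps * self.concentration_volumes[name]
        return out

    def ground_truth(self) -> GroundTruth:
        dV = float(np.prod(self.voxel_size_mm))
        counts = {name: 0 for name in LAYER_NAMES if name != "air"}
        in_vessel = self.vessel_id_volume >= 0
        labels = self.layer_volume[in_vessel]
        binc = np.bincount(labels, minlength=len(LAYER_NAMES))
        for i, name in enumerate(LAYER_NAMES):
            if name != "air":
                counts[name] = int(binc[i])
        mean_conc = {}
        for i, name in enumerate(LAYER_NAMES):
            if name == "air":
                continue
            sel = self.layer_volume == i
            n = int(sel.sum())
            mean_conc[name] = {
                comp: (float(vol[sel].mean()) if n else 0.0)
                for comp, vol in self.concentration_volumes.items()
            }
        cfg = self.config
        skin = (
            cfg.epidermis_thickness_mm
            + cfg.dermis_thickness_mm
            + cfg.dwat_thickness_mm
        )
        return GroundTruth(
            dermis_thickness_mm=cfg.dermis_thickness_mm,
            dwat_thickness_mm=cfg.dwat_thickness_mm,
            vessel_voxel_count_by_layer=counts,
            vessel_density_mm3_by_layer={k: v * dV for k, v in counts.items()},
            mean_concentration_by_layer=mean_conc,
            dwat_skin_percentage=100.0 * cfg.dwat_thickness_mm / skin,
        )


def lateral_sample_count(extent_mm: float, step_mm: float) -> int:
    """Raster positions covering [0, extent], both edges included."""
    return int(np.floor(extent_mm / step_mm + 1e-9)) + 1


def rasterize_vessel(
    vessel: Vessel,
    shape: tuple,
    voxel_size_mm: tuple,
) -> tuple:
    """Voxel indices whose centers lie within diameter/2 of the centerline.

    Returns ``(zz, xx, yy)`` index arrays.  A voxel belongs to the vessel if
    the distance from its center to the nearest centerline segment is at most
    the radius (point-to-segment distance).
    """
    dz, dx, dy = voxel_size_mm
    nz, nx, ny = shape
    r = vessel.diameter_um / 2000.0  # mm
    pts = np.asarray(vessel.centerline_mm, dtype=float)
    hit_z, hit_x, hit_y = [], [], []
    scale = np.array([dz, dx, dy])
    offset = np.array([0.5 * dz, 0.0, 0.0])  # axial centers at (k+0.5)dz
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.minimum(a, b) - r
        hi = np.maximum(a, b) + r
        i0 = np.maximum(np.floor((lo - offset) / scale), 0).astype(int)
        i1 = np.minimum(np.ceil((hi - offset) / scale), [nz - 1, nx - 1, ny - 1]).astype(int)
        if np.any(i1 < i0):
            continue
        zi = np.arange(i0[0], i1[0] + 1)
        xi = np.arange(i0[1], i1[1] + 1)
        yi = np.arange(i0[2], i1[2] + 1)
        Z, X, Y = np.meshgrid(zi, xi, yi, indexing="ij")
        centers = np.stack(
            [(Z + 0.5) * dz, X * dx, Y * dy], axis=-1
        )
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-18:
            t = np.zeros(centers.shape[:-1])
        else:
            t = np.clip(((centers - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = np.sum((centers - closest) ** 2, axis=-1)
        m = d2 <= r * r
        hit_z.append(Z[m])
        hit_x.append(X[m])
        hit_y.append(Y[m])
    if not hit_z:
        empty = np.array([], dtype=int)
        return empty, empty.copy(), empty.copy()
    return (
        np.concatenate(hit_z),
        np.concatenate(hit_x),
        np.concatenate(hit_y),
    )


def make_phantom(config: PhantomConfig, seed: int) -> Phantom:
    """Generate a layered-skin phantom; same (config, seed) is bit-identical."""
    config.validate()
    rng = np.random.default_rng(seed)
    dz, dx, dy = config.voxel_size_mm
    nx = lateral_sample_count(config.fast_extent_mm, dx)
    ny = lateral_sample_count(config.slow_extent_mm, dy)
    nz = int(round(config.depth_mm / dz))

    # conformal low-frequency undulation shared by all interfaces
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    phx, phy = rng.uniform(0, 2 * np.pi, size=2)
    k = 2 * np.pi / config.undulation_period_mm
    und = 0.5 * config.undulation_amplitude_mm * (
        np.sin(k * x[:, None] + phx) + np.sin(k * y[None, :] + phy)
    )

    surface = config.air_gap_mm + und
    epi_bottom = surface + config.epidermis_thickness_mm
    dermis_bottom = epi_bottom + config.dermis_thickness_mm
    dwat_bottom = dermis_bottom + config.dwat_thickness_mm
    pann_bottom = dwat_bottom + config.panniculus_thickness_mm
    boundaries = {
        "surface": surface,
        "epidermis_dermis": epi_bottom,
        "dermis_dwat": dermis_bottom,
        "dwat_panniculus": dwat_bottom,
        "panniculus_scwat": pann_bottom,
    }

    zc = (np.arange(nz) + 0.5) * dz
    stack = np.stack(
        [surface, epi_bottom, dermis_bottom, dwat_bottom, pann_bottom], axis=0
    )
    layer = np.sum(
        zc[:, None, None] >= stack[:, None, :, :], axis=0
    ).astype(np.uint8)

    # diffuse baselines with multiplicative heterogeneity (capillary bed /
    # tissue texture), shared across components
    texture = 1.0 + config.texture_amplitude * rng.uniform(-1.0, 1.0, (nz, nx, ny))
    conc = {
        comp: np.zeros((nz, nx, ny), dtype=np.float32)
        for comp in config.components
    }
    for li, lname in enumerate(LAYER_NAMES):
        base = config.baselines.get(lname, {})
        if not base:
            continue
        sel = layer == li
        for comp, value in base.items():
            if comp in conc and value != 0.0:
                conc[comp][sel] = (value * texture[sel]).astype(np.float32)

    # vessel placement: straight lateral segments at a random in-layer depth
    mean_top = {
        "dermis": config.air_gap_mm + config.epidermis_thickness_mm,
        "dwat": config.air_gap_mm
        + config.epidermis_thickness_mm
        + config.dermis_thickness_mm,
        "subcutis": config.air_gap_mm
        + config.epidermis_thickness_mm
        + config.dermis_thickness_mm
        + config.dwat_thickness_mm,
    }
    band_thickness = {
        "dermis": config.dermis_thickness_mm,
        "dwat": config.dwat_thickness_mm,
        "subcutis": config.panniculus_thickness_mm + 0.15,
    }
    area = config.fast_extent_mm * config.slow_extent_mm
    vessels: list[Vessel] = []
    vessel_id = np.full((nz, nx, ny), -1, dtype=np.int32)
    for (layer_name, cls) in sorted(config.vessels_per_mm2):
        density = config.vessels_per_mm2[(layer_name, cls)]
        n_vessels = int(round(density * area))
        lo_d, hi_d = config.diameter_ranges_um[cls]
        for _ in range(n_vessels):
            diameter = float(rng.uniform(lo_d, hi_d))
            r_mm = diameter / 2000.0
            top = mean_top[layer_name]
            thick = band_thickness[layer_name]
            if layer_name == "dermis" and cls == "large":
                # the deep dermal plexus runs along the dermis/hypodermis
                # junction: large dermal vessels are centered on the boundary
                z0 = top + thick + float(rng.uniform(-0.01, 0.01))
            elif layer_name == "dermis":
                # superficial plexus: upper and mid dermis
                z_lo = top + r_mm
                z_hi = top + 0.7 * thick
                z0 = float(rng.uniform(z_lo, max(z_hi, z_lo + 1e-6)))
            else:
                z_lo = top + r_mm + config.undulation_amplitude_mm
                z_hi = top + thick - r_mm - config.undulation_amplitude_mm
                z0 = (
                    float(rng.uniform(z_lo, z_hi))
                    if z_hi > z_lo
                    else top + thick / 2
                )
            p0 = rng.uniform([0, 0], [config.fast_extent_mm, config.slow_extent_mm])
            theta = rng.uniform(0, 2 * np.pi)
            length = float(rng.uniform(*config.vessel_length_mm))
            direction = np.array([np.cos(theta), np.sin(theta)])
            # finite segment p0 + t*direction, t in [-L/2, L/2], clipped to box
            tmin, tmax = -length / 2, length / 2
            for pi, di, hi_edge in (
                (p0[0], direction[0], config.fast_extent_mm),
                (p0[1], direction[1], config.slow_extent_mm),
            ):
                if abs(di) > 1e-12:
                    t0, t1 = (0.0 - pi) / di, (hi_edge - pi) / di
                    tmin = max(tmin, min(t0, t1))
                    tmax = min(tmax, max(t0, t1))
            if tmax <= tmin:
                continue
            a = p0 + tmin * direction
            b = p0 + tmax * direction
            centerline = np.array([[z0, a[0], a[1]], [z0, b[0], b[1]]])
            vessels.append(Vessel(centerline, diameter, cls))

    hbo2_c = config.blood_concentration * config.so2
    hb_c = config.blood_concentration * (1.0 - config.so2)
    for vid, vessel in enumerate(vessels):
        zz, xx, yy = rasterize_vessel(vessel, (nz, nx, ny), config.voxel_size_mm)
        if zz.size == 0:
            continue
        vessel_id[zz, xx, yy] = vid
        if "HbO2" in conc:
            conc["HbO2"][zz, xx, yy] = hbo2_c
        if "Hb" in conc:
            conc["Hb"][zz, xx, yy] = hb_c

    return Phantom(
        config=config,
        seed=int(seed),
        voxel_size_mm=config.voxel_size_mm,
        layer_boundaries_mm=boundaries,
        vessels=vessels,
        concentration_volumes=conc,
        layer_volume=layer,
        vessel_id_volume=vessel_id,
    )


def chow_like_config(**overrides) -> PhantomConfig:
    """Lean (chow-fed, sedentary) group: thin dWAT, well-vascularized."""
    cfg = PhantomConfig(**overrides)
    return cfg


def hfd_sedentary_like_config(**overrides) -> PhantomConfig:
    """Obese (high-fat-diet, sedentary) group: thicker dWAT with fewer,
    sparser dWAT vessels; dermis unchanged."""
    vessels = _default_vessels_per_mm2()
    vessels[("dwat", "small")] = 0.3
    vessels[("dwat", "large")] = 0.1
    defaults = dict(dwat_thickness_mm=0.70, vessels_per_mm2=vessels)
    defaults.update(overrides)
    return PhantomConfig(**defaults)
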