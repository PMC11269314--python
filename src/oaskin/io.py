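"""File formats: HDF5 for volumes and scans, TIFF for images, CSV for tables."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .phantom import Phantom
from .rsom import BandVolume, CompositeImage, RsomScan
from .spectra import WavelengthGrid
from .unmixing import MultispectralImage, UnmixResult


def save_phantom(phantom: Phantom, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = phantom.seed
        f.attrs["voxel_size_mm"] = phantom.voxel_size_mm
        f.attrs["config_json"] = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(phantom.config).items()
                if not isinstance(v, dict)
            }
        )
        g = f.create_group("concentrations")
        for name, vol in phantom.concentration_volumes.items():
            g.create_dataset(name, data=vol, compression="gzip")
        f.create_dataset("layer_volume", data=phantom.layer_volume, compression="gzip")
        f.create_dataset(
            "vessel_id_volume", data=phantom.vessel_id_volume, compression="gzip"
        )
        gb = f.create_group("layer_boundaries_mm")
        for name, bmap in phantom.layer_boundaries_mm.items():
            gb.create_dataset(name, data=bmap)
        if phantom.vessels:
            table = np.array(
                [
                    (
                        *v.centerline_mm[0],
                        *v.centerline_mm[-1],
                        v.diameter_um,
                        1 if v.size_class == "large" else 0,
                    )
                    for v in phantom.vessels
                ]
            )
        else:
            table = np.zeros((0, 8))
        f.create_dataset("vessels", data=table)


def save_scan(scan: RsomScan, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("alines", data=scan.alines, compression="gzip")
        for key in (
            "fs_MHz",
            "c_mm_per_us",
            "dx_mm",
            "dy_mm",
            "t0_us",
            "center_frequency_MHz",
        ):
            f.attrs[key] = getattr(scan, key)
        if scan.band_MHz is not None:
            f.attrs["band_MHz"] = scan.band_MHz


def load_scan(path) -> RsomScan:
    with h5py.File(path, "r") as f:
        band = tuple(f.attrs["band_MHz"]) if "band_MHz" in f.attrs else None
        return RsomScan(
            alines=f["alines"][()],
            fs_MHz=float(f.attrs["fs_MHz"]),
            c_mm_per_us=float(f.attrs["c_mm_per_us"]),
            dx_mm=float(f.attrs["dx_mm"]),
            dy_mm=float(f.attrs["dy_mm"]),
            t0_us=float(f.attrs["t0_us"]),
            center_frequency_MHz=float(f.attrs["center_frequency_MHz"]),
            band_MHz=band,
        )


def save_band_volume(volume: BandVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("volume", data=volume.V, compression="gzip")
        f.attrs["voxel_size_mm"] = volume.voxel_size_mm
        f.attrs["flattened"] = volume.flattened
        if volume.band_MHz is not None:
            f.attrs["band_MHz"] = volume.band_MHz


def load_band_volume(path) -> BandVolume:
    with h5py.File(path, "r") as f:
        band = tuple(f.attrs["band_MHz"]) if "band_MHz" in f.attrs else None
        return BandVolume(
            V=f["volume"][()],
            band_MHz=band,
            voxel_size_mm=tuple(f.attrs["voxel_size_mm"]),
            flattened=bool(f.attrs["flattened"]),
        )


def save_multispectral_tiff(image: MultispectralImage, path) -> None:
    """Multi-page TIFF (one page per wavelength) + sidecar wavelength header."""
    pages = np.moveaxis(image.S, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = str(path) + ".wavelengths.txt"
    grid = image.grid
    with open(sidecar, "w") as fh:
        fh.write(f"start_nm={grid.start_nm:g}\n")
        fh.write(f"stop_nm={grid.stop_nm:g}\n")
        fh.write(f"step_nm={grid.step_nm:g}\n")
        fh.write(f"pixel_size_mm={image.pixel_size_mm[0]:g},{image.pixel_size_mm[1]:g}\n")


def load_multispectral_tiff(path) -> MultispectralImage:
    pages = tifffile.imread(path)
    meta = {}
    with open(str(path) + ".wavelengths.txt") as fh:
        for line in fh:
            key, val = line.strip().split("=")
            meta[key] = val
    grid = WavelengthGrid(
        float(meta["start_nm"]), float(meta["stop_nm"]), float(meta["step_nm"])
    )
    px = tuple(float(x) for x in meta["pixel_size_mm"].split(","))
    return MultispectralImage(
        S=np.moveaxis(pages, 0, 2), pixel_size_mm=px, grid=grid
    )


def save_coefficient_tiff(result: UnmixResult, path) -> None:
    """Coefficient maps as multi-page TIFF, one page per component."""
    pages = np.moveaxis(result.C, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    with open(str(path) + ".components.txt", "w") as fh:
        fh.write("\n".join(result.component_names) + "\n")


def save_composite(image: CompositeImage, path) -> None:
    rgb8 = np.clip(image.rgb * 255.0, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, rgb8, photometric="rgb")


def load_spectra_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
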