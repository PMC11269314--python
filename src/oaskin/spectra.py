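"""Wavelength grids and chromophore absorption libraries.

The library is the design matrix of linear spectral unmixing: one column of
per-wavelength absorption values for each tissue chromophore (lipid, oxy- and
deoxy-hemoglobin, water, optionally the contrast dye ICG).  Absorption values
are in arbitrary units; unmixed coefficients inherit those units, which is why
all downstream readouts (lipid content, total blood volume) are relative
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KNOWN_COMPONENTS = ("lipid", "HbO2", "Hb", "H2O", "ICG")

#: Wavelength range (nm) in which the lipid absorption column must attain its
#: maximum; near-infrared lipid absorption peaks around 930 nm.
LIPID_PEAK_WINDOW_NM = (900.0, 960.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Equally spaced acquisition wavelengths, inclusive of both ends."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.stop_nm < self.start_nm:
            raise ValueError("stop_nm must be >= start_nm")
        n_steps = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                "stop_nm - start_nm must be an integer multiple of step_nm"
            )

    @property
    def values_nm(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return len(self.values_nm)


#: The acquisition grid of the multispectral (MSOT) arm: 700-960 nm in 10 nm
#: steps, i.e. 27 illumination wavelengths.
MSOT_GRID = WavelengthGrid(700.0, 960.0, 10.0)


@dataclass
class ChromophoreLibrary:
    """Per-wavelength absorption spectra of named chromophores.

    ``E`` has shape ``(n_wavelengths, n_components)`` and is the design matrix
    of :func:`oaskin.unmixing.unmix`.
    """

    component_names: list[str]
    E: np.ndarray
    grid: WavelengthGrid
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (len(self.grid), len(self.component_names)):
            raise ValueError(
                f"E has shape {self.E.shape}, expected "
                f"({len(self.grid)}, {len(self.component_names)})"
            )
        if np.any(self.E < 0):
            raise ValueError("absorption values must be non-negative")
        # no two identical columns (they would be unresolvable)
        for i in range(self.E.shape[1]):
            for j in range(i + 1, self.E.shape[1]):
                if np.array_equal(self.E[:, i], self.E[:, j]):
                    raise ValueError(
                        f"components {self.component_names[i]!r} and "
                        f"{self.component_names[j]!r} have identical spectra"
                    )
        if "lipid" in self.component_names:
            wl = self.grid.values_nm
            peak = wl[int(np.argmax(self.column("lipid")))]
            lo, hi = LIPID_PEAK_WINDOW_NM
            if not (lo <= peak <= hi):
                raise ValueError(
                    f"lipid column peaks at {peak:g} nm, outside "
                    f"[{lo:g}, {hi:g}] nm"
                )

    def column(self, name: str) -> np.ndarray:
        try:
            idx = self.component_names.index(name)
        except ValueError:
            raise KeyError(f"component {name!r} not in library") from None
        return self.E[:, idx]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.E))


def build_library(
    spectra_table: pd.DataFrame,
    grid: WavelengthGrid,
    components: list[str] | None = None,
    source_tag: str = "",
) -> ChromophoreLibrary:
    """Resample a spectra table onto an acquisition grid.

    ``spectra_table`` needs a ``wavelength_nm`` column plus one column per
    chromophore.  Components sampled on a different wavelength axis are
    linearly interpolated; a component whose samples do not cover the full
    grid raises an error naming it.
    """
    if "wavelength_nm" not in spectra_table.columns:
        raise ValueError("spectra table must have a 'wavelength_nm' column")
    if components is None:
        components = [c for c in spectra_table.columns if c != "wavelength_nm"]
    wl_tab = np.asarray(spectra_table["wavelength_nm"], dtype=float)
    order = np.argsort(wl_tab)
    wl_tab = wl_tab[order]
    wl = grid.values_nm
    cols = []
    for name in components:
        if name not in spectra_table.columns:
            raise ValueError(f"component {name!r} missing from spectra table")
        vals = np.asarray(spectra_table[name], dtype=float)[order]
        ok = np.isfinite(vals)
        if wl_tab[ok].min() > grid.start_nm or wl_tab[ok].max() < grid.stop_nm:
            raise ValueError(
                f"component {name!r} does not cover "
                f"[{grid.start_nm:g}, {grid.stop_nm:g}] nm"
            )
        cols.append(np.interp(wl, wl_tab[ok], vals[ok]))
    return ChromophoreLibrary(
        component_names=list(components),
        E=np.column_stack(cols),
        grid=grid,
        source_tag=source_tag,
    )


def synthetic_chromophore_table(wavelengths_nm: np.ndarray | None = None) -> pd.DataFrame:
    """Synthetic near-infrared absorption spectra for the five chromophores.

    These are smooth closed-form stand-ins with the qualitative features of
    the real spectra (deoxy-hemoglobin bump near 760 nm, oxy-hemoglobin rising
    toward 900 nm, lipid peak at 930 nm, water rising toward 975 nm, ICG peak
    at 800 nm), not literature values.  Arbitrary units.
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(680.0, 985.0, 5.0)
    wl = np.asarray(wavelengths_nm, dtype=float)

    def bump(center, width, amp=1.0):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    hb = 0.55 * np.exp(-(wl - 680.0) / 150.0) + bump(760.0, 22.0, 0.55) + 0.08
    hbo2 = 0.18 + 0.55 * (wl - 680.0) / 300.0 + bump(900.0, 60.0, 0.12)
    lipid = 0.05 + bump(930.0, 18.0, 1.0) + bump(760.0, 25.0, 0.12)
    h2o = 0.02 + bump(975.0, 40.0, 0.75) + bump(740.0, 30.0, 0.04)
    icg = bump(800.0, 32.0, 1.0) + 0.02
    return pd.DataFrame(
        {
            "wavelength_nm": wl,
            "lipid": lipid,
            "HbO2": hbo2,
            "Hb": hb,
            "H2O": h2o,
            "ICG": icg,
        }
    )


def default_library(
    grid: WavelengthGrid = MSOT_GRID,
    components: list[str] | None = None,
) -> ChromophoreLibrary:
    """The packaged synthetic library on the given grid."""
    if components is None:
        components = list(KNOWN_COMPONENTS)
    return build_library(
        synthetic_chromophore_table(), grid, components, source_tag="synthetic"
    )


def normalize_to_max(spectrum: np.ndarray) -> np.ndarray:
    """Scale a spectrum so its maximum equals 1 (display/comparison only).

    Never applied before unmixing: it destroys the amplitude information the
    coefficients carry.
    """
    s = np.asarray(spectrum, dtype=float)
    m = s.max() if s.size else 0.0
    if not np.isfinite(m) or m <= 0:
        raise ValueError("spectrum has no positive value to normalize by")
    return s / m
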