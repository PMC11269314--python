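"""Linear spectral unmixing of multi-wavelength optoacoustic images.

Per pixel, the measured spectrum S(λ) is modeled as a non-negative linear
mixture of library chromophore spectra,

    S(pixel, λ) = Σ_c E(λ, c) · C(pixel, c) + noise,

and the coefficients C are recovered by non-negative least squares (NNLS):
coefficients represent concentrations, so negative blood or lipid is
physically meaningless.  No fluence correction is applied — the fit is on raw
spectra and all coefficients are in arbitrary (relative) units.  Derived
readouts are the total blood volume surrogate TBV = Hb + HbO2 and the oxygen
saturation sO2 = HbO2 / (Hb + HbO2), the latter defined only where there is
enough blood signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .spectra import ChromophoreLibrary, WavelengthGrid


@dataclass
class MultispectralImage:
    """2-D image plane x wavelength stack of optoacoustic intensities (a.u.)."""

    S: np.ndarray  # (rows, cols, n_wavelengths)
    pixel_size_mm: tuple  # (row_mm, col_mm)
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 3 or self.S.shape[2] != len(self.grid):
            raise ValueError(
                f"S has shape {self.S.shape}; last axis must have "
                f"{len(self.grid)} wavelength planes"
            )


@dataclass
class UnmixResult:
    """Per-pixel non-negative mixture coefficients and fit residuals."""

    C: np.ndarray  # (rows, cols, n_components), >= 0
    residual_rms: np.ndarray  # (rows, cols)
    component_names: list

    def component(self, name: str) -> np.ndarray:
        try:
            idx = self.component_names.index(name)
        except ValueError:
            raise KeyError(f"component {name!r} not unmixed") from None
        return self.C[..., idx]


def _check_full_rank(E: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(E)
    if rank < E.shape[1]:
        # identify near-collinear pairs for the error message
        En = E / np.maximum(np.linalg.norm(E, axis=0), 1e-300)
        gram = np.abs(En.T @ En)
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if gram[i, j] > 1.0 - 1e-10
        ]
        raise ValueError(
            f"library design matrix is rank-deficient (rank {rank} < "
            f"{E.shape[1]}); collinear components: {pairs or 'unidentified'}"
        )


def unmix(
    image: MultispectralImage,
    library: ChromophoreLibrary,
    nonnegative: bool = True,
) -> UnmixResult:
    """Fit every pixel spectrum as a mixture of library spectra.

    ``nonnegative=False`` switches to ordinary (unconstrained) least squares
    for comparison; the default NNLS is what all derived readouts use.
    """
    if image.grid != library.grid:
        raise ValueError(
            f"image grid {image.grid} does not match library grid {library.grid}"
        )
    E = library.E
    _check_full_rank(E, library.component_names)
    rows, cols, n_wl = image.S.shape
    flat = image.S.reshape(-1, n_wl)
    n_comp = E.shape[1]
    C = np.empty((flat.shape[0], n_comp))
    if nonnegative:
        for i, s in enumerate(flat):
            C[i], _ = scipy.optimize.nnls(E, s)
    else:
        C = np.linalg.lstsq(E, flat.T, rcond=None)[0].T
    resid = flat - C @ E.T
    residual_rms = np.sqrt(np.mean(resid**2, axis=1)).reshape(rows, cols)
    return UnmixResult(
        C=C.reshape(rows, cols, n_comp),
        residual_rms=residual_rms,
        component_names=list(library.component_names),
    )


def total_blood_volume(result: UnmixResult) -> np.ndarray:
    """TBV map: sum of oxy- and deoxy-hemoglobin coefficients."""
    return result.component("Hb") + result.component("HbO2")


def oxygen_saturation(
    result: UnmixResult, tbv_floor: float | None = None
) -> np.ndarray:
    """sO2 map: HbO2 / (Hb + HbO2), NaN where TBV is below the floor.

    ``tbv_floor`` defaults to 1% of the image's maximum TBV: oxygen
    saturation is ill-defined where there is essentially no blood signal, and
    such pixels are excluded (NaN) from any ROI statistic.
    """
    tbv = total_blood_volume(result)
    if tbv_floor is None:
        tbv_floor = 0.01 * float(tbv.max())
    if tbv_floor <= 0:
        raise ValueError("tbv_floor must be positive")
    hbo2 = result.component("HbO2")
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.where(tbv >= tbv_floor, hbo2 / tbv, np.nan)
    return so2


def roi_average(value_map: np.ndarray, rois: list) -> float:
    """Mean over ROIs of the per-ROI mean of defined (non-NaN) pixels.

    With exactly three ROIs this reproduces the per-subject statistic of the
    emulated protocol (each data point averaged from three ROIs).
    """
    if len(rois) < 1:
        raise ValueError("at least one ROI is required")
    value_map = np.asarray(value_map, dtype=float)
    means = []
    for i, roi in enumerate(rois):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != value_map.shape:
            raise ValueError(f"ROI {i} shape {roi.shape} != map {value_map.shape}")
        vals = value_map[roi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {i} contains no defined pixels")
        means.append(float(vals.mean()))
    return float(np.mean(means))
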