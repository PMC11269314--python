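"""Scalar readouts and group statistics.

Vessel density follows the N x dV statistic: N is the number of voxels inside
the analyzed layer mask whose intensity exceeds 20% of the reference maximum,
dV the voxel volume, so the density is the tissue volume (mm^3) occupied by
vascular signal.  The reference maximum defaults to the maximum inside the
analyzed layer (making dermis and dWAT densities independently normalized);
``reference_scope="volume"`` switches to the global maximum.

The dWAT share of the skin is a column-wise extent ratio on an unmixed
cross-sectional lipid map: per image column inside the skin ROI, the dWAT
extent is the contiguous run of lipid coefficients above a relative threshold
below the dermis band, divided by the full skin extent of that column.

Group summaries report mean ± SEM per group and compare groups with Student's
t-test (two groups) or one-way ANOVA followed by Tukey's HSD (more than two),
with significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .rsom import BandVolume
from .segmentation import LayerMask
from .unmixing import UnmixResult


@dataclass
class VesselDensityResult:
    layer_name: str
    N: int
    dV_mm3: float
    density_mm3: float
    threshold_fraction: float
    reference_max: float


@dataclass
class MetricsRecord:
    subject_id: str
    group: str
    layer: str
    metric: str
    value: float
    units: str

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("units must be non-empty")


def vessel_density(
    volume: BandVolume,
    mask: LayerMask,
    threshold_fraction: float = 0.2,
    reference_scope: str = "layer",
) -> VesselDensityResult:
    """N x dV: count voxels above ``threshold_fraction`` of the reference max.

    Scaling all intensities by a positive constant leaves N (and the density)
    unchanged; an all-zero region yields density 0.
    """
    if not volume.flattened:
        raise ValueError("volume must be flattened before quantification")
    if mask.mask.shape != volume.V.shape:
        raise ValueError("mask grid does not match the volume grid")
    m = mask.mask
    if not m.any():
        raise ValueError(f"layer mask {mask.layer_name!r} is empty")
    if reference_scope == "layer":
        ref = float(volume.V[m].max())
    elif reference_scope == "volume":
        ref = float(volume.V.max())
    else:
        raise ValueError(f"unknown reference_scope {reference_scope!r}")
    if ref <= 0:
        n = 0
    else:
        n = int(np.count_nonzero(volume.V[m] > threshold_fraction * ref))
    dV = volume.dV_mm3
    return VesselDensityResult(
        layer_name=mask.layer_name,
        N=n,
        dV_mm3=dV,
        density_mm3=n * dV,
        threshold_fraction=threshold_fraction,
        reference_max=ref,
    )


def _longest_true_run(mask_1d: np.ndarray) -> tuple:
    """(start, length) of the longest True run; (0, 0) if none."""
    best_start, best_len, start = 0, 0, None
    for i, v in enumerate(mask_1d):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(mask_1d) - start > best_len:
        best_start, best_len = start, len(mask_1d) - start
    return best_start, best_len


def dwat_percentage(
    unmix: UnmixResult,
    skin_roi: np.ndarray,
    lipid_threshold_fraction: float = 0.5,
) -> float:
    """Percentage of the skin occupied by dWAT, from a cross-sectional
    lipid coefficient map.

    ``skin_roi`` is a boolean (rows=depth, cols=fast) mask spanning the full
    skin (epidermis + dermis + dWAT) in the image plane.  Per column, the
    dWAT extent is the longest contiguous run of lipid pixels above
    ``lipid_threshold_fraction`` times the column maximum (the lipid-rich
    dermal fat band below the blood-rich dermis); the ratio to the column's
    skin extent is averaged over columns.
    """
    lipid = unmix.component("lipid")
    roi = np.asarray(skin_roi, dtype=bool)
    if roi.shape != lipid.shape:
        raise ValueError("skin ROI shape does not match the coefficient maps")
    if not roi.any():
        raise ValueError("skin ROI is empty")
    if lipid[roi].max() <= 0:
        warnings.warn("no lipid-positive pixels inside the skin ROI", stacklevel=2)
        return 0.0
    ratios = []
    for col in range(lipid.shape[1]):
        rows = np.nonzero(roi[:, col])[0]
        if rows.size == 0:
            continue
        vals = lipid[rows, col]
        col_max = vals.max()
        if col_max <= 0:
            ratios.append(0.0)
            continue
        above = vals > lipid_threshold_fraction * col_max
        _, run_len = _longest_true_run(above)
        ratios.append(run_len / rows.size)
    return float(100.0 * np.mean(ratios))


def auto_skin_roi(
    unmix: UnmixResult,
    lipid_threshold_fraction: float = 0.5,
    signal_fraction: float = 0.05,
) -> np.ndarray:
    """Automatic skin ROI on a cross-sectional unmixing result.

    Emulates the expert-drawn ROI: per column, the skin top is the first row
    with appreciable total signal, and the skin bottom is the end of the
    first supra-threshold lipid run below it (the dWAT band; deeper fat is
    separated from it by the low-lipid panniculus).  Columns where no lipid
    band is found are excluded.
    """
    total = unmix.C.sum(axis=2)
    lipid = unmix.component("lipid")
    n_rows, n_cols = total.shape
    roi = np.zeros((n_rows, n_cols), dtype=bool)
    for col in range(n_cols):
        tcol = total[:, col]
        if tcol.max() <= 0:
            continue
        top = int(np.argmax(tcol > signal_fraction * tcol.max()))
        lcol = lipid[:, col]
        if lcol.max() <= 0:
            continue
        above = lcol > lipid_threshold_fraction * lcol.max()
        above[:top] = False
        idx = np.nonzero(above)[0]
        if idx.size == 0:
            continue
        start = idx[0]
        end = start
        while end + 1 < n_rows and above[end + 1]:
            end += 1
        roi[top : end + 1, col] = True
    return roi


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def group_summary(records) -> dict:
    """Per-(metric, layer) group means ± SEM and group comparisons.

    Two groups are compared with an independent two-sample t-test, more than
    two with one-way ANOVA followed by Tukey's HSD post-hoc pairs.  Groups of
    size one are summarized but excluded from tests (noted in the output).
    """
    df = records_to_frame(records)
    required = {"subject_id", "group", "layer", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    summaries, comparisons = [], []
    for (metric, layer), sub in df.groupby(["metric", "layer"], sort=True):
        for group, vals in sub.groupby("group", sort=True)["value"]:
            v = vals.to_numpy(dtype=float)
            summaries.append(
                {
                    "metric": metric,
                    "layer": layer,
                    "group": group,
                    "n": len(v),
                    "mean": float(v.mean()),
                    "sem": float(v.std(ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1
                    else np.nan,
                }
            )
        groups = {g: v.to_numpy(dtype=float) for g, v in sub.groupby("group")["value"]}
        testable = {g: v for g, v in groups.items() if len(v) >= 2}
        skipped = sorted(set(groups) - set(testable))
        note = f"groups skipped (n=1): {skipped}" if skipped else ""
        names = sorted(testable)
        if len(names) == 2:
            t, p = scipy.stats.ttest_ind(testable[names[0]], testable[names[1]])
            comparisons.append(
                {
                    "metric": metric,
                    "layer": layer,
                    "test": "t-test",
                    "comparison": f"{names[0]} vs {names[1]}",
                    "statistic": float(t),
                    "p_value": float(p),
                    "stars": significance_stars(float(p)),
                    "note": note,
                }
            )
        elif len(names) > 2:
            f, p = scipy.stats.f_oneway(*(testable[g] for g in names))
            comparisons.append(
                {
                    "metric": metric,
                    "layer": layer,
                    "test": "anova",
                    "comparison": " vs ".join(names),
                    "statistic": float(f),
                    "p_value": float(p),
                    "stars": significance_stars(float(p)),
                    "note": note,
                }
            )
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            values = np.concatenate([testable[g] for g in names])
            labels = np.concatenate(
                [np.repeat(g, len(testable[g])) for g in names]
            )
            tk = pairwise_tukeyhsd(values, labels)
            res = tk.summary().data[1:]
            for row in res:
                g1, g2, meandiff, p_adj = row[0], row[1], row[2], row[3]
                comparisons.append(
                    {
                        "metric": metric,
                        "layer": layer,
                        "test": "tukey",
                        "comparison": f"{g1} vs {g2}",
                        "statistic": float(meandiff),
                        "p_value": float(p_adj),
                        "stars": significance_stars(float(p_adj)),
                        "note": note,
                    }
                )
        elif note:
            comparisons.append(
                {
                    "metric": metric,
                    "layer": layer,
                    "test": "none",
                    "comparison": "",
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "stars": "",
                    "note": note,
                }
            )
    return {
        "summary": pd.DataFrame(summaries),
        "comparisons": pd.DataFrame(comparisons),
    }
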