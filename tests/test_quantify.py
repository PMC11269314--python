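import numpy as np

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from oaskin.quantify import (
    MetricsRecord,
    auto_skin_roi,
    dwat_percentage,
    group_summary,
    significance_stars,
    vessel_density,
)
from oaskin.rsom import BandVolume
from oaskin.segmentation import LayerMask
from oaskin.unmixing import UnmixResult


def band_volume(V, dV_edge=0.1):
    return BandVolume(
        V=np.asarray(V, dtype=float),
        band_MHz=None,
        voxel_size_mm=(dV_edge, dV_edge, dV_edge),
        flattened=True,
    )


def full_mask(shape, name="dwat"):
    return LayerMask(mask=np.ones(shape, dtype=bool), layer_name=name)


class TestVesselDensity:
    def test_hand_counted_toy_region(self):
        # 4x4x4 region, dV = 0.001 mm^3, exactly 3 voxels above 20% of max
        V = np.full((4, 4, 4), 0.1)
        V[0, 0, 0] = 10.0  # the reference max
        V[1, 1, 1] = 5.0
        V[2, 2, 2] = 3.0
        # threshold = 2.0; values above: 10, 5, 3 -> N = 3
        res = vessel_density(band_volume(V), full_mask(V.shape))
        assert res.N == 3
        assert res.density_mm3 == pytest.approx(3 * 0.001)
        assert res.density_mm3 == res.N * res.dV_mm3

    def test_all_zero_region_density_zero(self):
        V = np.zeros((3, 3, 3))
        res = vessel_density(band_volume(V), full_mask(V.shape))
        assert res.N == 0 and res.density_mm3 == 0.0

    def test_intensity_scaling_invariance(self, rng):
        V = rng.random((6, 5, 4))
        r1 = vessel_density(band_volume(V), full_mask(V.shape))
        r2 = vessel_density(band_volume(10.0 * V), full_mask(V.shape))
        assert r1.N == r2.N and r1.density_mm3 == r2.density_mm3

    def test_matches_bruteforce_loop_on_random_pairs(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(3, 7, size=3))
            V = rng.random(shape)
            mask = rng.random(shape) < 0.5
            mask.flat[0] = True
            res = vessel_density(
                band_volume(V), LayerMask(mask=mask, layer_name="x")
            )
            ref = V[mask].max()
            n = 0
            for idx in np.ndindex(shape):
                if mask[idx] and V[idx] > 0.2 * ref:
                    n += 1
            assert res.N == n
            assert res.density_mm3 == pytest.approx(n * res.dV_mm3)

    def test_empty_mask_rejected(self, rng):
        V = rng.random((3, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            vessel_density(
                band_volume(V), LayerMask(np.zeros((3, 3, 3), bool), "dwat")
            )

    def test_reference_scope_volume(self):
        V = np.full((4, 2, 2), 0.1)
        V[0, 0, 0] = 10.0
        mask = np.zeros(V.shape, dtype=bool)
        mask[1:] = True  # excludes the bright voxel
        res_layer = vessel_density(band_volume(V), LayerMask(mask, "m"), 0.2, "layer")
        res_vol = vessel_density(band_volume(V), LayerMask(mask, "m"), 0.2, "volume")
        assert res_layer.N == mask.sum()  # all at 0.1 > 0.2*0.1
        assert res_vol.N == 0  # nothing above 0.2*10

    def test_adding_a_vessel_never_decreases_density(self, rng):
        # same reference max in both volumes (held by a fixed bright voxel)
        V = rng.random((6, 6, 6))
        V[0, 0, 0] = 50.0
        V2 = V.copy()
        V2[3, 3, 3] = 40.0  # a new vessel voxel
        m = full_mask(V.shape)
        d1 = vessel_density(band_volume(V), m).density_mm3
        d2 = vessel_density(band_volume(V2), m).density_mm3
        assert d2 >= d1


def unmix_result(lipid, others=0.0):
    lipid = np.asarray(lipid, dtype=float)
    C = np.stack(
        [lipid, np.full_like(lipid, others), np.full_like(lipid, others)],
        axis=-1,
    )
    return UnmixResult(
        C=C, residual_rms=np.zeros(lipid.shape),
        component_names=["lipid", "HbO2", "Hb"],
    )


class TestDwatPercentage:
    def test_half_depth_band_gives_50_percent(self):
        # 40-row skin; lipid band occupies rows 20..39 (half) in every column
        lipid = np.zeros((40, 15))
        lipid[20:, :] = 1.0
        roi = np.ones((40, 15), dtype=bool)
        pct = dwat_percentage(unmix_result(lipid), roi)
        assert pct == pytest.approx(50.0, abs=2 * 100 / 40)

    def test_zero_lipid_gives_zero_with_warning(self):
        lipid = np.zeros((10, 5))
        roi = np.ones((10, 5), dtype=bool)
        with pytest.warns(UserWarning, match="lipid"):
            assert dwat_percentage(unmix_result(lipid), roi) == 0.0

    def test_doubling_lipid_leaves_percentage_unchanged(self, rng):
        lipid = rng.random((30, 8)) ** 3
        roi = np.ones((30, 8), dtype=bool)
        p1 = dwat_percentage(unmix_result(lipid), roi)
        p2 = dwat_percentage(unmix_result(2.0 * lipid), roi)
        assert p1 == pytest.approx(p2)

    def test_percentage_in_range(self, rng):
        lipid = rng.random((25, 12))
        roi = rng.random((25, 12)) < 0.8
        roi[0] = True
        pct = dwat_percentage(unmix_result(lipid), roi)
        assert 0.0 <= pct <= 100.0

    def test_auto_roi_spans_signal_to_lipid_band(self):
        # columns: signal from row 5; lipid band rows 20-29; fat again at 40+
        # separated by a dark gap (the panniculus analogue)
        lipid = np.zeros((60, 6))
        lipid[20:30, :] = 1.0
        lipid[40:55, :] = 0.9
        res = unmix_result(lipid, others=0.0)
        res.C[5:30, :, 1] = 0.5  # blood signal defines the skin top
        roi = auto_skin_roi(res)
        rows = np.nonzero(roi[:, 0])[0]
        assert rows[0] == 5 and rows[-1] == 29


class TestGroupSummary:
    def _records(self, groups: dict, metric="thickness", layer="dwat"):
        recs = []
        for g, values in groups.items():
            for i, v in enumerate(values):
                recs.append(MetricsRecord(f"{g}_{i}", g, layer, metric, v, "mm"))
        return recs

    def test_identical_groups_t_zero_p_one(self):
        out = group_summary(self._records({"a": [1, 2, 3], "b": [1, 2, 3]}))
        row = out["comparisons"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)
        assert row["stars"] == "ns"

    def test_sem_closed_form(self):
        out = group_summary(self._records({"a": [2.0, 4.0, 6.0]}))
        row = out["summary"].iloc[0]
        assert row["mean"] == pytest.approx(4.0)
        assert row["sem"] == pytest.approx(2.0 / np.sqrt(3.0))

    def test_three_groups_use_anova_and_tukey(self, rng):
        groups = {g: rng.normal(i, 1, size=6).tolist()
                  for i, g in enumerate(["a", "b", "c"])}
        out = group_summary(self._records(groups))
        tests = set(out["comparisons"]["test"])
        assert "anova" in tests and "tukey" in tests
        assert len(out["comparisons"][out["comparisons"].test == "tukey"]) == 3

    def test_singleton_group_skipped_with_notice(self):
        out = group_summary(self._records({"a": [1.0, 2.0], "b": [5.0]}))
        comp = out["comparisons"]
        assert (comp["note"].str.contains("n=1")).any()
        summary = out["summary"]
        assert set(summary["group"]) == {"a", "b"}

    def test_anova_type_I_error_rate_near_nominal(self):
        # 3 groups from one distribution: rejection rate ~ 5% over 1000 sims
        rng = np.random.default_rng(2024)
        n_reject = 0
        n_sim = 1000
        for _ in range(n_sim):
            g = [rng.normal(0, 1, 8) for _ in range(3)]
            _, p = scipy.stats.f_oneway(*g)
            n_reject += p < 0.05
        assert 0.04 <= n_reject / n_sim <= 0.06

    @pytest.mark.parametrize(
        "p,stars",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "ns"), (np.nan, "")],
    )
    def test_significance_stars(self, p, stars):
        assert significance_stars(p) == stars

    def test_units_required(self):
        with pytest.raises(ValueError, match="units"):
            MetricsRecord("s", "g", "dwat", "thickness", 1.0, "")


@settings(derandomize=True, max_examples=30)
@given(
    st.integers(min_value=2, max_value=5).flatmap(
        lambda k: st.lists(
            st.floats(min_value=0.01, max_value=10, allow_nan=False),
            min_size=k * k,
            max_size=k * k,
        ).map(lambda vals: (k, vals))
    )
)
def test_density_threshold_is_relative_property(args):
    k, vals = args
    V = np.array(vals).reshape(k, k, 1)
    vol = band_volume(V)
    mask = full_mask(V.shape)
    r1 = vessel_density(vol, mask)
    r2 = vessel_density(band_volume(V * 3.7), mask)
    assert r1.N == r2.N
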