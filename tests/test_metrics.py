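"""Per-branch descriptors: TAWSS, OSI, percentiles, SA80, Reynolds, CoV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import carotidflow as cf
from carotidflow.core import WallScalarSeries
from carotidflow.metrics import branch_mean_series, pooled_exposure, \
    systolic_values
from conftest import wall_series


class TestTimeAverage:
    def test_constant_series(self):
        s = wall_series(np.tile([[1.0, 0, 0]], (3, 5, 1)))
        assert np.allclose(cf.time_average(s), 1.0)

    def test_scaled_waveform(self):
        w = np.array([0.2, 1.0, 0.5, 0.3])
        tau = np.zeros((1, 4, 3)); tau[0, :, 0] = 2.0 * w
        assert cf.time_average(wall_series(tau))[0] == \
            pytest.approx(2.0 * w.mean())

    def test_mean_of_magnitudes_not_magnitude_of_mean(self):
        tau = np.zeros((1, 2, 3))
        tau[0, 0] = [1, 0, 0]; tau[0, 1] = [0, 1, 0]
        assert cf.time_average(wall_series(tau))[0] == pytest.approx(1.0)

    def test_invalid_vertices_are_nan(self):
        s = wall_series(np.ones((2, 3, 3)), valid=[True, False])
        out = cf.time_average(s)
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestOSI:
    def test_constant_direction_is_zero(self):
        tau = np.tile([[0.4, 0.1, 0.0]], (1, 8, 1)) \
            * np.linspace(0.5, 2, 8)[None, :, None]
        assert cf.osi(wall_series(tau))[0] == pytest.approx(0.0, abs=1e-12)

    def test_full_reversal_is_half(self):
        t = np.arange(16) / 16
        tau = np.zeros((1, 16, 3))
        tau[0, :, 0] = np.sin(2 * np.pi * t)
        assert cf.osi(wall_series(tau))[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_frame_worked_example(self):
        tau = np.zeros((1, 2, 3))
        tau[0, 0] = [1, 0, 0]; tau[0, 1] = [0, 1, 0]
        assert cf.osi(wall_series(tau))[0] == pytest.approx(0.1464, abs=1e-4)

    def test_zero_shear_flagged_invalid(self):
        out = cf.osi(wall_series(np.zeros((1, 4, 3))))
        assert np.isnan(out[0])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_osi_always_in_range(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.normal(size=(8, 6, 3))
        out = cf.osi(wall_series(tau))
        ok = np.isfinite(out)
        assert np.all(out[ok] >= 0) and np.all(out[ok] <= 0.5)

    def test_gap_to_magnitude_of_mean(self):
        """TAWSS (mean of magnitudes) >= |mean vector| -- the triangle
        inequality whose slack is what OSI measures."""
        rng = np.random.default_rng(3)
        tau = rng.normal(size=(50, 9, 3))
        s = wall_series(tau)
        ta = cf.time_average(s)
        mom = np.linalg.norm(tau.mean(axis=1), axis=1)
        assert np.all(ta >= mom - 1e-12)


class TestBranchDescriptives:
    def test_worked_percentiles(self):
        vals = np.arange(1.0, 11.0)
        labels = np.ones(10, dtype=int)
        df = cf.branch_descriptives(vals, labels)
        row = df.iloc[0]
        assert row["min"] == pytest.approx(1.9)
        assert row["median"] == pytest.approx(5.5)
        assert row["max"] == pytest.approx(9.1)

    def test_constant_field_degenerate(self):
        df = cf.branch_descriptives(np.full(20, 2.5),
                                    np.ones(20, dtype=int))
        row = df.iloc[0]
        assert row["min"] == row["median"] == row["max"] == 2.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 2, 40)
        labels = np.repeat([1, 2], 20)
        a = cf.branch_descriptives(vals, labels)
        p = rng.permutation(40)
        b = cf.branch_descriptives(vals[p], labels[p])
        pd.testing.assert_frame_equal(a, b)

    def test_percentile_ordering_always_holds(self):
        rng = np.random.default_rng(5)
        df = cf.branch_descriptives(rng.normal(size=200),
                                    np.ones(200, dtype=int))
        row = df.iloc[0]
        assert row["min"] <= row["median"] <= row["max"]

    def test_small_branch_marked_incomplete(self):
        df = cf.branch_descriptives(np.ones(5), np.ones(5, dtype=int))
        assert not df.iloc[0]["complete"]


class TestSystolic:
    def test_waveform_peak_frame_identified(self, default_y):
        spec, mask, _ = default_y
        flow = cf.FlowSpec(n_timeframes=40)  # peak at phase 0.15 -> frame 6
        field = cf.make_velocity_field(spec, flow, mask=mask)
        assert cf.systolic_frame(field, mask) == 6

    def test_constant_flow_systolic_equals_time_average(self):
        tau = np.tile([[0.5, 0, 0]], (12, 4, 1))
        s = wall_series(tau)
        labels = np.ones(12, dtype=int)
        sys_val = systolic_values(s, labels, frame=0)["CCA"]
        assert sys_val == pytest.approx(
            np.nanmean(cf.time_average(s)[labels == 1]))

    def test_branch_mean_series_shape(self):
        s = wall_series(np.random.default_rng(0).normal(size=(9, 5, 3)))
        labels = np.repeat([1, 2, 3], 3)
        bm = branch_mean_series(s, labels)
        assert list(bm.columns) == ["CCA", "ICA", "ECA"]
        assert len(bm) == 5


class TestSA80:
    @staticmethod
    def _table(values, areas=None, n_bif=2):
        values = np.asarray(values, dtype=float)
        areas = np.ones_like(values) if areas is None else areas
        bif = np.arange(len(values)) % n_bif
        return pd.DataFrame({"bifurcation": bif, "branch": "CCA",
                             "tawss": values, "area": areas})

    def test_uniform_distribution_degenerates(self):
        res = cf.sa80(self._table(np.full(20, 0.8)))
        assert res.thresholds["CCA"] == pytest.approx(0.8)
        assert np.allclose(res.exposure["exposure_pct"], 100.0)

    def test_ten_equal_patches(self):
        res = cf.sa80(self._table(np.arange(1.0, 11.0)))
        assert res.thresholds["CCA"] == pytest.approx(8.0)
        pooled = pooled_exposure(self._table(np.arange(1.0, 11.0)),
                                 res.thresholds)
        assert pooled["CCA"] == pytest.approx(80.0)

    def test_pooled_exposure_within_one_vertex_share(self):
        rng = np.random.default_rng(6)
        values = rng.lognormal(0, 0.6, 500)
        areas = rng.uniform(0.5, 1.5, 500)
        tab = self._table(values, areas, n_bif=5)
        res = cf.sa80(tab)
        pooled = pooled_exposure(tab, res.thresholds)["CCA"]
        max_share = 100 * areas.max() / areas.sum()
        assert 80.0 - 1e-9 <= pooled <= 80.0 + max_share

    def test_single_bifurcation_rejected(self):
        with pytest.raises(ValueError, match="2 bifurcations"):
            cf.sa80(self._table(np.arange(10.0), n_bif=1))

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="area"):
            cf.sa80(pd.DataFrame({"bifurcation": [0, 1], "branch": "CCA",
                                  "tawss": [1.0, 2.0]}))


class TestReynolds:
    def test_zero_velocity(self):
        assert cf.reynolds(8.0, np.array([0.0]))[0] == 0

    def test_printed_example(self):
        assert cf.reynolds(10.0, np.array([0.1]))[0] == \
            pytest.approx(331.25)

    def test_linear_in_velocity_and_diameter(self):
        v = np.array([0.25])
        assert cf.reynolds(8.0, 2 * v)[0] == \
            pytest.approx(2 * cf.reynolds(8.0, v)[0])
        assert cf.reynolds(16.0, v)[0] == \
            pytest.approx(2 * cf.reynolds(8.0, v)[0])

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            cf.reynolds(0.0, np.array([0.1]))


class TestCoV:
    def test_constant_data(self):
        assert cf.coefficient_of_variation([3.0, 3.0, 3.0]) == 0

    def test_worked_example(self):
        assert cf.coefficient_of_variation([2.0, 4.0, 6.0]) == \
            pytest.approx(50.0)

    def test_scale_invariance(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert cf.coefficient_of_variation(x) == pytest.approx(
            cf.coefficient_of_variation([7 * v for v in x]))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cf.coefficient_of_variation([-1.0, 1.0])


class TestSummarize:
    def test_branch_rows_and_invariants(self, default_y):
        spec, mask, _ = default_y
        flow = cf.FlowSpec(n_timeframes=6)
        field = cf.make_velocity_field(spec, flow, mask=mask)
        fine = cf.upsample(field, 0.55, dtype=np.float32)
        surf = cf.extract_surface(mask, spec.spacing)
        fm = cf.FluidModel()
        series = cf.compute_wss(fine, surf, fm, cf.WSSProbe(), mask,
                                mask_spacing=spec.spacing)
        tke = 5.0 * (mask > 0)
        nwt = cf.nwtke(tke, surf, mask, spec.spacing)
        nwt = WallScalarSeries(np.repeat(nwt.values, 6, axis=1), nwt.valid,
                               fine.times, nwt.kernel_radius)
        summary, timecourse, verts = cf.summarize_bifurcation(
            0, series, nwt, surf, field, mask,
            {cf.CCA: 8.7, cf.ICA: 7.5, cf.ECA: 5.7}, 49.5, fm)
        assert set(summary["branch"]) == {"CCA", "ICA", "ECA"}
        assert np.all(summary["osi"].between(0, 0.5))
        assert np.all(summary["min_wss_pa"] <= summary["max_wss_pa"])
        assert np.allclose(summary["tanwtke_jm3"], 5.0)
        assert len(timecourse) == 3 * 6
        assert {"bifurcation", "branch", "tawss", "area"} <= \
            set(verts.columns)
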