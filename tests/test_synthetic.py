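"""Phantom generators: masks, velocity fields, IVSD, corruption."""

import numpy as np
import pytest

import carotidflow as cf
from carotidflow.core import voxel_centers
from carotidflow.synthetic import (BranchSpec, Hotspot, cylinder_phantom,
                                   make_cohort)


class TestBifurcationMask:
    def test_cylinder_cross_section_matches_brute_force_count(self, cylinder):
        spec, mask, _ = cylinder
        # independent oracle: count grid points inside the analytic circle
        b = spec.branches[0]
        centers = voxel_centers(spec.shape, spec.spacing)
        for k in range(8, 20):  # interior slices
            sl = centers[:, :, k, :]
            inside = np.sum((sl[..., 0] - b.origin[0]) ** 2
                            + (sl[..., 1] - b.origin[1]) ** 2
                            <= b.radius ** 2)
            assert (mask[:, :, k] > 0).sum() == inside
            # and close to the analytic area / voxel area
            expect = np.pi * b.radius ** 2 / (spec.spacing[0]
                                              * spec.spacing[1])
            assert abs(inside - expect) <= 12  # boundary voxels

    def test_zero_length_daughters_give_single_branch(self):
        spec = cf.symmetric_y_phantom()
        for b in spec.branches:
            if b.label != cf.CCA:
                b.length = 0.0
        mask, truth = cf.make_bifurcation_mask(spec)
        assert set(np.unique(mask)) == {0, cf.CCA}
        assert truth["bifurcation_point_mm"] is None

    def test_symmetric_half_angles_sum_to_bifurcation_angle(self):
        spec = cf.symmetric_y_phantom(angle=50.0, ica_fraction=0.5)
        _, truth = cf.make_bifurcation_mask(spec)
        assert truth["bifurcation_angle_deg"] == pytest.approx(50.0)

    def test_branch_exiting_grid_is_reported_by_name(self):
        spec = cylinder_phantom(radius=3.0, length=30.0)
        spec.branches[0].length = 200.0
        with pytest.raises(ValueError, match="CCA"):
            cf.make_bifurcation_mask(spec)

    def test_daughter_labels_partition_lumen(self, default_y):
        spec, mask, _ = default_y
        assert set(np.unique(mask)) == {0, cf.CCA, cf.ICA, cf.ECA}

    def test_mask_deterministic(self, default_y):
        spec, mask, _ = default_y
        mask2, _ = cf.make_bifurcation_mask(spec)
        assert np.array_equal(mask, mask2)


class TestVelocityField:
    def test_parabolic_profile_centerline_and_wall(self, cylinder):
        spec, mask, _ = cylinder
        flow = cf.FlowSpec(v_max=0.5, n_timeframes=4)
        field = cf.make_velocity_field(spec, flow, mask=mask)
        b = spec.branches[0]
        centers = voxel_centers(spec.shape, spec.spacing)
        r = np.sqrt((centers[..., 0] - b.origin[0]) ** 2
                    + (centers[..., 1] - b.origin[1]) ** 2)
        w = flow.scales()
        # centreline: the innermost voxel column carries ~v_max * w(t)
        i, j = np.unravel_index(np.argmin(r[:, :, 15]), r[:, :, 15].shape)
        expect = flow.v_max * (1 - (r[i, j, 15] / b.radius) ** 2) * w
        assert np.allclose(field.data[i, j, 15, :, 2], expect)
        # no-slip: velocity is zero outside, small at the wall ring
        assert np.all(field.data[mask == 0] == 0)

    def test_volumetric_flow_matches_half_peak_times_area(self, cylinder):
        spec, mask, _ = cylinder
        flow = cf.FlowSpec(v_max=0.5, n_timeframes=3)
        field = cf.make_velocity_field(spec, flow, mask=mask)
        # numerically integrate axial velocity over one interior slice
        va = spec.spacing[0] * spec.spacing[1]  # mm^2
        q = field.data[:, :, 15, :, 2].sum(axis=(0, 1)) * va  # mm^2 m/s
        expect = 0.5 * flow.v_max * np.pi * 3.0 ** 2 * flow.scales()
        assert np.allclose(q, expect, rtol=0.05)

    def test_plug_profile_is_uniform(self, cylinder):
        spec, mask, _ = cylinder
        flow = cf.FlowSpec(v_max=0.3, n_timeframes=1, profile="plug",
                           waveform=((0, 1), (1, 1)))
        field = cf.make_velocity_field(spec, flow, mask=mask)
        speeds = field.data[mask > 0][:, 0, 2]
        assert np.allclose(speeds, 0.3)

    def test_unknown_profile_kind_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            cf.FlowSpec(profile="womersley")


class TestIVSD:
    def test_no_hotspots_all_zero(self, cylinder):
        spec, mask, _ = cylinder
        assert cf.make_ivsd_field(mask, spec.spacing, []).sum() == 0

    def test_hotspot_tke_value(self, cylinder):
        spec, mask, _ = cylinder
        center = np.array([8.0, 8.0, 20.0])
        ivsd = cf.make_ivsd_field(mask, spec.spacing,
                                  [Hotspot(center, 3.0, 0.1)])
        tke = cf.tke_from_ivsd(ivsd, rho=1060.0, lumen_mask=mask)
        idx = tuple(np.round(center / spec.spacing - 0.5).astype(int))
        assert tke[idx] == pytest.approx(15.9)

    def test_overlapping_hotspots_take_pointwise_maximum(self, cylinder):
        spec, mask, _ = cylinder
        c = np.array([8.0, 8.0, 20.0])
        hs = [Hotspot(c, 3.0, 0.05), Hotspot(c, 3.0, 0.12),
              Hotspot(c, 3.0, 0.12)]
        ivsd = cf.make_ivsd_field(mask, spec.spacing, hs)
        idx = tuple(np.round(c / spec.spacing - 0.5).astype(int))
        assert ivsd[idx + (0,)] == pytest.approx(0.12)

    def test_zero_outside_lumen_and_isotropic(self, cylinder):
        spec, mask, _ = cylinder
        ivsd = cf.make_ivsd_field(mask, spec.spacing,
                                  [Hotspot((8.0, 8.0, 20.0), 6.0, 0.1)])
        assert np.all(ivsd[mask == 0] == 0)
        assert np.array_equal(ivsd[..., 0], ivsd[..., 1])
        assert np.array_equal(ivsd[..., 0], ivsd[..., 2])

    def test_negative_sigma_rejected(self, cylinder):
        spec, mask, _ = cylinder
        with pytest.raises(ValueError, match="non-negative"):
            cf.make_ivsd_field(mask, spec.spacing,
                               [Hotspot((8, 8, 20), 3.0, -0.1)])


class TestCorruption:
    def test_identity_corruption(self, cylinder):
        spec, mask, _ = cylinder
        field = cf.make_velocity_field(spec, cf.FlowSpec(n_timeframes=2),
                                       mask=mask)
        out = cf.corrupt(field, cf.CorruptionSpec())
        assert np.array_equal(out.data, field.data)

    def test_constant_offset_reaches_background(self, cylinder):
        spec, mask, _ = cylinder
        field = cf.make_velocity_field(spec, cf.FlowSpec(n_timeframes=2),
                                       mask=mask)
        coeffs = np.zeros((3, 35))
        coeffs[:, 0] = [0.01, -0.02, 0.03]  # constant term
        out = cf.corrupt(field, cf.CorruptionSpec(offset_coeffs=coeffs))
        bg = out.data[mask == 0]
        assert np.allclose(bg[:, :, 0], 0.01)
        assert np.allclose(bg[:, :, 1], -0.02)
        assert np.allclose(bg[:, :, 2], 0.03)

    def test_noise_sd_matches_request(self):
        spec = cylinder_phantom(radius=3.0, length=40.0, spacing=(0.8,) * 3)
        mask, _ = cf.make_bifurcation_mask(spec)
        field = cf.make_velocity_field(spec, cf.FlowSpec(n_timeframes=4),
                                       mask=mask)
        out = cf.corrupt(field, cf.CorruptionSpec(noise_sd=0.05, seed=7))
        bg = out.data[mask == 0].ravel()
        assert bg.size >= 1e5
        assert np.std(bg) == pytest.approx(0.05, rel=0.02)

    def test_seed_makes_corruption_bit_reproducible(self, cylinder):
        spec, mask, _ = cylinder
        field = cf.make_velocity_field(spec, cf.FlowSpec(n_timeframes=2),
                                       mask=mask)
        c = cf.CorruptionSpec(noise_sd=0.05, seed=11)
        assert np.array_equal(cf.corrupt(field, c).data,
                              cf.corrupt(field, c).data)


class TestCohort:
    def test_cohort_deterministic_and_within_physiology(self):
        a = make_cohort(4, seed=3)
        b = make_cohort(4, seed=3)
        for ca, cb in zip(a, b):
            assert ca.flow.v_max == cb.flow.v_max
            assert np.array_equal(ca.corruption.offset_coeffs,
                                  cb.corruption.offset_coeffs)
            assert ca.flow.v_max <= 1.2  # below the VENC analogue
            assert ca.vessel.true_angle() == pytest.approx(
                cb.vessel.true_angle())
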