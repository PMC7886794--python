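"""Carreau-Yasuda viscosity, the smoothing-spline wall derivative, and
the full WSS computation against the Poiseuille oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.interpolate import make_smoothing_spline

import carotidflow as cf
from carotidflow.synthetic import cylinder_phantom
from carotidflow.wss import spline_wall_slope, wall_shear_vector


FM = cf.FluidModel()


class TestCarreauYasuda:
    def test_zero_shear_limit_is_mu0(self):
        assert cf.carreau_yasuda(0.0, FM) == FM.mu0

    def test_infinite_shear_limit_is_mu_inf(self):
        assert cf.carreau_yasuda(1e9, FM) == pytest.approx(FM.mu_inf,
                                                           rel=1e-3)

    def test_formula_at_100_per_second(self):
        # independent one-line evaluation of the constitutive law
        g = 100.0
        expect = FM.mu_inf + (FM.mu0 - FM.mu_inf) * (
            1 + (FM.lam * g) ** FM.a) ** ((FM.n - 1) / FM.a)
        assert cf.carreau_yasuda(g, FM) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(4.7e-3, rel=0.01)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            cf.carreau_yasuda(-1.0, FM)

    @given(st.floats(min_value=0, max_value=1e6))
    def test_monotone_and_bounded(self, g):
        mu = float(cf.carreau_yasuda(g, FM))
        assert FM.mu_inf <= mu <= FM.mu0
        assert float(cf.carreau_yasuda(g + 1.0, FM)) <= mu + 1e-15


class TestSmoothingSpline:
    def test_matches_scipy_at_larger_n(self):
        # scipy's penalised smoothing spline is the independent oracle
        # (it requires n >= 5, which the 3-point wall probe never has)
        x = np.linspace(0, 3, 7)
        y = np.sin(x) + 0.05 * np.cos(7 * x)
        for lam in (1e-4, 1e-2, 0.5):
            ours = spline_wall_slope(x, y, lam)
            ref = make_smoothing_spline(x, y, lam=lam).derivative()(0.0)
            assert ours == pytest.approx(float(ref), rel=1e-6)

    def test_reproduces_straight_line_for_any_penalty(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 0.7 * x
        for lam in (0.0, 1e-3, 1.0, 100.0):
            assert spline_wall_slope(x, y, lam) == pytest.approx(0.7,
                                                                 abs=1e-9)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            spline_wall_slope([0.0, 1.0], [0.0, 1.0], 0.0)


class TestWallShearVector:
    def test_zero_samples_give_zero_stress(self):
        samples = [(1.0, np.zeros(3)), (2.0, np.zeros(3)),
                   (3.0, np.zeros(3))]
        tau, valid = wall_shear_vector(samples, FM, cf.WSSProbe(),
                                       np.array([0.0, 0.0, 1.0]))
        assert valid and np.allclose(tau, 0)

    def test_linear_tangential_samples_constant_viscosity(self):
        # slope s (in 1/s) purely tangential: |tau| = mu * s
        slope_mm = 2e-4  # m/s per mm -> 0.2 1/s
        normal = np.array([1.0, 0.0, 0.0])
        samples = [(d, np.array([0.0, 0.0, slope_mm * d]))
                   for d in (1.0, 2.0, 3.0)]
        tau, valid = wall_shear_vector(samples, FM, cf.WSSProbe(),
                                       normal, viscosity="constant")
        assert valid
        assert np.linalg.norm(tau) == pytest.approx(FM.mu_ref * 0.2,
                                                    rel=1e-9)
        assert abs(tau @ normal) < 1e-12

    def test_fewer_than_two_samples_invalid(self):
        tau, valid = wall_shear_vector([(1.0, np.ones(3))], FM,
                                       cf.WSSProbe(), np.array([1., 0, 0]))
        assert not valid and np.allclose(tau, 0)


class TestSampleWallVelocity:
    def test_zero_field_samples_zero(self, cylinder):
        spec, mask, _ = cylinder
        field = cf.VelocityField(np.zeros((*spec.shape, 1, 3)), spec.spacing,
                                 np.array([0.0]), 1.0)
        surf = cf.extract_surface(mask, spec.spacing)
        out = cf.sample_wall_velocity(field, surf.vertices[0],
                                      surf.normals[0], cf.WSSProbe(), mask,
                                      spec.spacing)
        assert all(np.allclose(v, 0) for _, v in out)

    def test_parabolic_profile_sampled_along_true_radial(self, cylinder):
        spec, mask, _ = cylinder
        flow = cf.FlowSpec(v_max=0.4, n_timeframes=1, waveform=((0, 1),
                                                                (1, 1)))
        field = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask),
                            0.55)
        b = spec.branches[0]
        # a wall point on the true cylinder surface, probing inward
        vertex = b.origin + np.array([b.radius, 0, 15.0])
        normal = np.array([-1.0, 0.0, 0.0])
        out = cf.sample_wall_velocity(field, vertex, normal, cf.WSSProbe(),
                                      mask, spec.spacing)
        for d, v in out:
            expect = flow.v_max * (1 - ((b.radius - d) / b.radius) ** 2)
            assert v[2] == pytest.approx(expect, abs=0.05 * flow.v_max)

    def test_thin_branch_truncates_probe(self):
        spec = cylinder_phantom(radius=1.0, length=20.0, spacing=(0.5,) * 3)
        mask, _ = cf.make_bifurcation_mask(spec)
        field = cf.VelocityField(np.zeros((*spec.shape, 1, 3)), spec.spacing,
                                 np.array([0.0]), 1.0)
        surf = cf.extract_surface(mask, spec.spacing)
        mid = np.argmin(np.abs(surf.vertices[:, 2] - 10.0))
        out = cf.sample_wall_velocity(field, surf.vertices[mid],
                                      surf.normals[mid], cf.WSSProbe(),
                                      mask, spec.spacing)
        # a 3 mm probe cannot fit 3 in-lumen points in a 2 mm-wide tube
        assert len(out) < 3


class TestComputeWSS:
    def test_poiseuille_median_within_fifteen_percent(self, poiseuille_wss):
        p = poiseuille_wss
        med = np.median(p["series"].magnitudes()[p["series"].valid, 0])
        assert med == pytest.approx(p["analytic"], rel=0.15)

    def test_stress_is_everywhere_tangential(self, poiseuille_wss):
        s = poiseuille_wss["series"]
        n = poiseuille_wss["surface"].normals
        dot = np.abs(np.einsum("vtc,vc->vt", s.values, n))
        mag = s.magnitudes()
        ok = mag > 1e-12
        assert np.all(dot[ok] < 1e-6 * mag[ok])

    def test_quasi_steady_wss_tracks_waveform(self, cylinder):
        spec, mask, _ = cylinder
        flow = cf.FlowSpec(v_max=0.4, n_timeframes=8)
        field = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask),
                            0.55)
        surf = cf.extract_surface(mask, spec.spacing)
        series = cf.compute_wss(field, surf, FM, cf.WSSProbe(), mask,
                                mask_spacing=spec.spacing,
                                viscosity="constant")
        med = np.median(series.magnitudes()[series.valid], axis=0)
        r = np.corrcoef(med, flow.scales())[0, 1]
        assert r > 0.99

    def test_linearity_in_peak_velocity(self, cylinder, poiseuille_wss):
        spec, mask, _ = cylinder
        flow = cf.FlowSpec(v_max=0.8, n_timeframes=1, waveform=((0, 1),
                                                                (1, 1)))
        field = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask),
                            0.55)
        series = cf.compute_wss(field, poiseuille_wss["surface"], FM,
                                cf.WSSProbe(), mask,
                                mask_spacing=spec.spacing,
                                viscosity="constant")
        ratio = series.magnitudes()[:, 0] \
            / np.maximum(poiseuille_wss["series"].magnitudes()[:, 0], 1e-30)
        valid = series.valid & poiseuille_wss["series"].valid
        assert np.allclose(ratio[valid], 2.0, rtol=0.01)

    def test_invalid_fraction_small_on_default_phantom(self, default_y):
        spec, mask, _ = default_y
        flow = cf.FlowSpec(n_timeframes=1, waveform=((0, 1), (1, 1)))
        field = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask),
                            0.55, dtype=np.float32)
        surf = cf.extract_surface(mask, spec.spacing)
        series = cf.compute_wss(field, surf, FM, cf.WSSProbe(), mask,
                                mask_spacing=spec.spacing)
        assert series.invalid_fraction < 0.05

    def test_mismatched_frames_rejected(self, cylinder):
        spec, mask, _ = cylinder
        field = cf.VelocityField(np.zeros((4, 4, 4, 1, 3)), (1.0, 1.0, 1.0),
                                 np.array([0.0]), 1.0)
        surf = cf.extract_surface(mask, spec.spacing)
        with pytest.raises(ValueError, match="coordinate frames"):
            cf.compute_wss(field, surf, FM, cf.WSSProbe(), mask,
                           mask_spacing=spec.spacing)


def test_poiseuille_error_decreases_with_refinement():
    """Recovery error shrinks monotonically as the acquisition voxel is
    halved twice (fixed 1.1 mm surface-smoothing scale)."""
    errors = []
    for vox in (2.2, 1.1, 0.55):
        spec = cylinder_phantom(radius=3.0, length=30.0, spacing=(vox,) * 3)
        mask, _ = cf.make_bifurcation_mask(spec)
        flow = cf.FlowSpec(v_max=0.4, n_timeframes=1, waveform=((0, 1),
                                                                (1, 1)))
        fine = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask),
                           vox / 2)
        sig = 1.1 / vox
        surf = cf.extract_surface(mask, spec.spacing, smoothing_sigma=sig,
                                  check_normals=False)
        series = cf.compute_wss(fine, surf, FM, cf.WSSProbe(), mask,
                                mask_spacing=spec.spacing,
                                viscosity="constant", mask_sigma=sig)
        med = np.median(series.magnitudes()[series.valid, 0])
        errors.append(abs(med - 0.85333) / 0.85333)
    assert errors[0] > errors[1] > errors[2]
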