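import numpy as np
import pytest
from hypothesis import settings

import carotidflow as cf
from carotidflow.synthetic import cylinder_phantom

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cylinder():
    """Straight tube, R = 3 mm, 1.1 mm isotropic voxels: the Poiseuille
    oracle geometry."""
    spec = cylinder_phantom(radius=3.0, length=30.0, spacing=(1.1,) * 3)
    mask, truth = cf.make_bifurcation_mask(spec)
    return spec, mask, truth


@pytest.fixture(scope="session")
def default_y():
    """Default carotid Y-phantom (cohort-mean diameters and angle)."""
    spec = cf.symmetric_y_phantom()
    mask, truth = cf.make_bifurcation_mask(spec)
    return spec, mask, truth


@pytest.fixture(scope="session")
def poiseuille_wss(cylinder):
    """Steady Poiseuille flow, constant viscosity, upsampled to 0.55 mm,
    with the WSS series computed once for the whole session."""
    spec, mask, _ = cylinder
    flow = cf.FlowSpec(v_max=0.4, n_timeframes=1, waveform=((0, 1), (1, 1)))
    field = cf.make_velocity_field(spec, flow, mask=mask)
    fine = cf.upsample(field, 0.55)
    surface = cf.extract_surface(mask, spec.spacing)
    fm = cf.FluidModel()
    series = cf.compute_wss(fine, surface, fm, cf.WSSProbe(), mask,
                            mask_spacing=spec.spacing, viscosity="constant")
    return {"spec": spec, "mask": mask, "flow": flow, "field": fine,
            "surface": surface, "fm": fm, "series": series,
            "analytic": 2 * fm.mu_ref * flow.v_max / 3e-3}


def wall_series(tau, valid=None, times=None):
    """Small helper to build a WallVectorSeries from a raw (nv, nt, 3)."""
    tau = np.asarray(tau, dtype=float)
    if valid is None:
        valid = np.ones(tau.shape[0], dtype=bool)
    if times is None:
        times = np.arange(tau.shape[1], dtype=float)
    return cf.WallVectorSeries(tau, np.asarray(valid), np.asarray(times))
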