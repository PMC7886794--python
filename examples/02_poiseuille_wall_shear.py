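"""Wall shear stress on a straight tube, checked against Poiseuille.

For steady laminar flow in a cylinder the wall shear stress is known in
closed form, tau = 2 mu v_max / R. This script runs the full WSS chain
(voxelise -> cubic up-sample -> surface -> inward-normal probe ->
smoothing-spline slope -> viscosity) in constant-viscosity mode and
compares the vertex-median estimate with the analytic value.
"""

import numpy as np

import carotidflow as cf
from carotidflow.synthetic import cylinder_phantom

spec = cylinder_phantom(radius=3.0, length=30.0, spacing=(1.1,) * 3)
mask, _ = cf.make_bifurcation_mask(spec)
flow = cf.FlowSpec(v_max=0.4, n_timeframes=1, waveform=((0, 1), (1, 1)))
field = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask), 0.55)
surface = cf.extract_surface(mask, spec.spacing)
fm = cf.FluidModel()

series = cf.compute_wss(field, surface, fm, cf.WSSProbe(), mask,
                        mask_spacing=spec.spacing, viscosity="constant")
median = np.median(series.magnitudes()[series.valid, 0])
analytic = 2 * fm.mu_ref * flow.v_max / 3e-3  # R = 3 mm -> 3e-3 m

print(f"vertices: {surface.n_vertices}, "
      f"invalid: {100 * series.invalid_fraction:.1f}%")
print(f"analytic wall shear stress: {analytic:.3f} Pa")
print(f"vertex-median estimate:     {median:.3f} Pa "
      f"({100 * (median - analytic) / analytic:+.1f}%)")

# At 1.1 mm voxels the estimate lands within ~10% of the analytic
# value; the residual bias combines the sub-voxel placement of the
# extracted wall with the natural smoothing spline's boundary
# behaviour, both inherent to this family of MRI WSS estimators.
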