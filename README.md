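# carotidflow

Wall shear stress (WSS), near-wall turbulent kinetic energy (nwTKE),
oscillatory shear index (OSI) and morphometry of the carotid bifurcation,
computed from time-resolved three-directional (4D Flow MRI-style) velocity
fields — together with a synthetic phantom generator that provides analytic
ground truth for every quantity in the chain.

## Who this is for

Hemodynamics researchers who estimate wall stresses from 4D Flow MRI of the
carotid arteries and want a tested, reproducible reimplementation of the
standard analysis chain: background phase-offset correction, cubic
up-sampling, lumen surface and centerline extraction, probe-based WSS with a
shear-thinning viscosity, spherical-kernel nwTKE, per-branch descriptors
(TAWSS, TAnwTKE, OSI, SA80, Reynolds numbers) and the cohort-level Spearman
correlation and t-test tables. Because in vivo validation data are rarely
shareable, the package ships a first-class synthetic module: bifurcating
vessel phantoms with pulsatile Poiseuille flow, intravoxel-SD turbulence
fields, Gaussian noise and degree-4 polynomial phase offsets — all with
exact ground truth, so every estimator can be checked against a closed form.

## The methods in brief

**WSS.** At each vertex of the triangulated lumen wall, velocity is
interpolated at 3 points spaced 1 mm apart along the inward normal (probe
length 3 mm). With velocity defined to be zero at the wall, a natural cubic
smoothing spline is fitted through the anchor and the samples per velocity
component; its slope at the wall gives the velocity-gradient vector g. After
removing the wall-normal component, the shear rate is γ̇ = |g_t| and

    τ = μ(γ̇) · g_t,       μ(γ̇) = μ∞ + (μ0 − μ∞)·[1 + (λγ̇)^a]^((n−1)/a)

with Carreau–Yasuda whole-blood constants μ0 = 0.056 Pa·s, μ∞ = 0.00345 Pa·s,
λ = 3.313 s, a = 2, n = 0.3568 (all configurable; a constant-viscosity mode
exists for analytic checks).

**nwTKE.** Per-direction intravoxel velocity standard deviations σᵢ give the
turbulence energy density TKE = (ρ/2)·Σσᵢ² (J/m³); at each wall vertex,
nwTKE is the mean TKE over lumen voxels within a 2.5 mm sphere.

**Whole-cycle metrics.** TAWSS = time mean of |τ(t)|;
OSI = ½(1 − ‖∫τ dt‖ / ∫‖τ‖ dt) ∈ [0, 0.5]; per-branch "minimum"/"maximum"
are the 10th/90th percentiles (outlier-robust); the SA80 threshold is the
pooled TAWSS value below which 80% of cohort surface area lies, and
per-subject exposure is the branch area fraction under it;
Re = ρ·v̄·D/μ with ρ = 1060 kg/m³ and μ = 3.2×10⁻³ Pa·s.

**Geometry.** Branch centerlines are minimal-cost paths through the lumen
voxel graph (cost penalised by inverse squared wall distance), re-centred by
circle fits to the outer wall; branch diameter is the mean equivalent-circle
diameter 2√(A/π); the bifurcation angle is measured between vectors from
each daughter's point nearest the bifurcation to the arc-length midpoint of
that daughter's centreline.

## A worked example

```python
import numpy as np
import carotidflow as cf
from carotidflow.synthetic import cylinder_phantom

spec = cylinder_phantom(radius=3.0, length=30.0, spacing=(1.1,) * 3)
mask, _ = cf.make_bifurcation_mask(spec)
flow = cf.FlowSpec(v_max=0.4, n_timeframes=1, waveform=((0, 1), (1, 1)))
field = cf.upsample(cf.make_velocity_field(spec, flow, mask=mask), 0.55)
surface = cf.extract_surface(mask, spec.spacing)
series = cf.compute_wss(field, surface, cf.FluidModel(), cf.WSSProbe(),
                        mask, mask_spacing=spec.spacing, viscosity="constant")
print(np.median(series.magnitudes()[series.valid, 0]))
```

prints `0.930` Pa against the analytic Poiseuille value
2μv_max/R = `0.853` Pa — a +9% deviation at 1.1 mm voxels, typical of this
estimator family at MRI resolution (see `docs/methods.md`). The scripts in
`examples/` walk through each capability the same way: phantom construction,
the Poiseuille check above, nwTKE around a turbulence hotspot, morphometry
recovery, and the five-subject cohort pipeline, e.g.

```
$ python examples/04_morphometry.py
branch   estimated   true   error (mm)
  CCA       9.61      9.20   +0.41
  ICA       7.92      8.10   -0.18
  ECA       5.15      5.20   -0.05
bifurcation angle: 62.0 deg (true 62.0, error +0.0)
```

A thin CLI wraps the same functions
(`carotid-wallstress simulate|preprocess|geometry|stats|all`); `all
--config config.yaml` runs the full synthetic-cohort pipeline and writes the
summary, SA80 and correlation tables plus a manifest with seeds and
checksums, bit-reproducibly for a fixed seed.

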