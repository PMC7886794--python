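# Methods

This note documents the models, numerical choices and limitations behind
`carotidflow`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic phantoms do and do not tell
you about real 4D Flow MRI data.

## Coordinate and grid conventions

World coordinates are millimetres; the voxel with 0-based index (i, j, k)
has its centre at ((i, j, k) + 0.5)·spacing. Velocities are m/s, stresses
Pa, TKE J/m³. NIfTI affines written by the package encode exactly this
convention. Timeframes are uniformly spaced over one cardiac cycle, and
time integrals use uniform frame weights.

## Synthetic phantoms

A phantom is a union of cylindrical branches: a common carotid (CCA) along
one axis and two daughters (ICA, ECA) leaving its distal end at prescribed
half-angles, so the ground-truth bifurcation angle is their sum. A voxel
belongs to the lumen iff its *centre* lies inside the analytic tube union
(no partial volume), which keeps voxel-count area oracles exact up to
boundary voxels. Voxels inside both daughter tubes at the carina are
assigned to the branch whose axis is nearer in radius-normalised distance,
ties to the ICA — an arbitrary but documented rule.

Default geometry follows the carotid morphometry of a mid-size
atherosclerosis cohort: branch diameters 8.7/7.5/5.7 mm (CCA/ICA/ECA),
bifurcation angle 49.5°, sampled at 1.1 × 1.1 × 1.2 mm with 40 timeframes —
the acquisition geometry of a carotid 4D Flow exam. The cohort generator
draws diameters and angle from Normal distributions with the corresponding
cohort SDs (1.1/1.4/1.0 mm; 13.4°), truncated at ±2 SD, angles clipped to
[25°, 75°]; peak velocities ~N(0.8, 0.15) m/s clipped to [0.5, 1.1], below
the 1.2 m/s VENC analogue. At small angles with wide daughters the two
tubes overlap far past the carina; the phantom builder extends the daughter
length so that at least ~1.5 daughter diameters of cleanly separated vessel
exist — as in a real carotid, where the branches run well past the bulb.

Pulsatility is quasi-steady: a fixed spatial profile (parabolic Poiseuille
or plug) scaled by a periodic waveform with a sharp systolic peak at phase
0.15 (frame 6 of 40) and a diastolic plateau at ~0.35 of peak. This choice
gives closed-form wall shear at every timeframe — the point of the phantom —
at the cost of Womersley physics: no phase lag across the lumen, no
flattened oscillatory profiles, and perfect inter-branch synchrony. Tests
passing on these phantoms therefore validate the *estimators*
(interpolation, surface, probe, spline, kernel, statistics), not the
physiological realism of any particular flow.

Turbulence is emulated by spherical isotropic "hotspots" of intravoxel
velocity standard deviation (IVSD) placed in the daughters just distal to
the bifurcation, where flow separation puts turbulence in vivo, over a
uniform low background floor (3% of v_max) representing baseline
measurement fluctuation. Real post-stenotic turbulence is anisotropic and
spatially structured; the hotspots make no claim of physiological fidelity
— they exist so the kernel arithmetic can be verified and so cohort
correlations have realistic spread. In the pipeline, IVSD is modulated over
the cycle by the flow waveform shifted two frames later, reflecting that
turbulent energy peaks during deceleration after peak systole.

Measurement corruption adds (a) i.i.d. Gaussian velocity noise and (b) a
background phase offset: per velocity component a full 3-variable
polynomial of total degree 4 (35 terms) over coordinates normalised to
[−1, 1] per axis, constant in time, added everywhere including the static
background — precisely the artifact the correction stage removes. All
generators are bit-reproducible given a seed.

## Preprocessing

**Phase-offset correction.** Per component, a degree-4 polynomial is fitted
by weighted least squares (SVD; default weights 1, a weight map is
accepted) to the *time-averaged* velocity of static-tissue voxels and
subtracted from all voxels at all timeframes. Offsets are reconstruction
artifacts and approximately steady, so a time-constant surface is fitted
rather than one per frame. In the synthetic pipeline the static mask is the
background minus a 2-voxel dilation of the lumen, excluding partial-volume
shells. The fit needs at least 35 static voxels and raises on a
rank-deficient design. Standard errors from the residual variance accompany
the coefficients; with the injected offsets of the corruption model the
noise-free recovery is exact to machine precision (same basis), and with
0.05 m/s noise the coefficients land within ~3 standard errors.

**Up-sampling.** Each component is interpolated per timeframe with an
interpolating cubic B-spline onto a grid of the same physical extent
(default target 0.55 mm, half the in-plane acquisition voxel). Values at
source voxel centres are preserved; a linear field is reproduced exactly in
the interior; near the wall the velocity has a kink (zero outside), so
interpolation error concentrates within ~2 source voxels of the boundary.

## Surface and lumen membership

The wall is the 0.5 isosurface (marching cubes) of the Gaussian-smoothed
binary lumen, default σ = 1 voxel. The *same* smoothed indicator defines
point-in-lumen membership (trilinear interpolation ≥ 0.5), so "inside the
lumen" and "inside the extracted wall" agree by construction; this matters
for the probe-validity rule below. Inward normals come from the marching
cubes gradient, oriented so a 0.5 mm inward step lands in the lumen
(verified for ≥ 99% of vertices, else an error). Per-vertex area is one
third of the incident triangle areas, so areas sum to the mesh area; vertex
branch labels are inherited from the nearest labelled voxel.

## Wall shear stress

Three probe points at 1, 2, 3 mm along the inward normal (configurable
count/length); probe points outside the lumen are dropped and a vertex with
fewer than 2 surviving points is flagged invalid and excluded from every
statistic. Velocity at probe points is *linear* interpolation on the
already cubic-up-sampled grid — a second cubic stage would compound
overshoot at the wall. With the wall anchored at zero, a natural cubic
smoothing spline (penalised least squares, penalty λ∫f″², solved in the
Green–Silverman band form since only 3–4 points are involved) is fitted per
component and differentiated at the wall. The default penalty λ = 10⁻³ mm³
is light smoothing: it leaves straight-line data exact (the penalty
annihilates affine functions) while damping single-point noise. The slope
is a linear functional of the sampled velocities, so one weight vector per
distinct probe layout turns the whole surface into a matrix product.

The shear rate entering the Carreau–Yasuda law is the magnitude of the
*tangential* gradient (the normal component is removed first); whether the
normal component should contribute is ambiguous in this estimator family,
and the tangential convention keeps τ = μγ̇ self-consistent. Carreau–Yasuda
constants are standard whole-blood values (μ0 = 0.056 Pa·s,
μ∞ = 0.00345 Pa·s, λ = 3.313 s, a = 2, n = 0.3568); the constant-viscosity
mode (μ = 3.2×10⁻³ Pa·s) exists because it makes the estimator homogeneous
of degree 1 in the velocity field, enabling exact linearity and
proportionality checks.

**Known bias.** On the steady Poiseuille cylinder (R = 3 mm, v_max =
0.4 m/s, 1.1 mm voxels up-sampled to 0.55 mm) the vertex-median estimate is
+9% of the analytic 0.853 Pa. Two effects compete: the smoothed isosurface
sits slightly inside the true wall (≈ σ²·κ curvature shrink), biasing the
slope up, while the natural spline's boundary condition (f″ = 0 at the
wall) underestimates the slope of a parabolic profile by ~10%. The second
effect is inherent to smoothing-spline WSS estimators and is the documented
reason such estimators underestimate at high resolution. In the refinement
study (voxels 2.2 → 1.1 → 0.55 mm) the smoothing scale is held at a fixed
1.1 mm *physical* width so the surface definition is resolution-independent;
recovery error then falls monotonically (≈24% → 9% → 4%).

## Near-wall TKE

TKE = (ρ/2)(σ₁² + σ₂² + σ₃²) per voxel, masked to the lumen. nwTKE at a
vertex is the *unweighted mean* of TKE over lumen voxels whose centres lie
within the kernel radius (default 2.5 mm); only lumen voxels enter because
background TKE is undefined and would dilute wall values. Vertices with an
empty kernel are invalid; a radius below half the largest voxel dimension
is rejected outright. The implementation (KD-tree + sparse kernel matrix)
matches a brute-force sphere enumeration exactly, which the tests assert.

## Per-branch metrics

* TAWSS is the time mean of |τ(t)| (mean of magnitudes), the convention
  consistent with reporting OSI separately; the triangle-inequality gap to
  the magnitude-of-mean is exactly what OSI rescales.
* OSI = ½(1 − ‖mean_t τ‖ / mean_t ‖τ‖), clipped to [0, 0.5]; undefined
  (NaN) where the cycle-integrated shear is zero.
* Branch "minimum"/"maximum" are the 10th/90th percentiles over valid
  vertices with linear interpolation, *unweighted* — the descriptors
  describe vertices — whereas SA80 is *area-weighted*, because its
  definition is explicitly in surface area. The SA80 threshold is the
  smallest pooled TAWSS at which the cumulative area fraction reaches 80%
  (a step rule, so pooled exposure equals 80% up to one vertex's share).
* The systolic timeframe is the frame maximising the CCA lumen-mean
  velocity magnitude — an operational definition, since phantoms and scans
  have no independent ECG ground truth. "Peak" values are the maximum over
  frames of the branch-mean waveform; per-frame P90/P10 series are also
  emitted, so both readings of "maximum over time" are available under
  distinct names (`max_*` vs `peak_*`).
* Reynolds numbers use ρ = 1060 kg/m³ and μ = 3.2×10⁻³ Pa·s with the
  branch mean diameter and per-frame lumen-mean speed. (A printed blood
  density of "1.060 kg/m³" in the source literature is read as the obvious
  unit slip for 1060 kg/m³.)
* CoV = 100·SD/mean with sample SD (n−1); undefined for zero mean.

## Morphometry

Each branch is traced independently inside its own label region: a
minimal-cost path through the 26-connected voxel graph with edge cost
step/(mean wall distance)², the standard freespace-centerline construction,
runs from the branch tip to the end nearest the bifurcation. Points are
then re-centred by fitting a circle (linear Kasa least squares) to the
branch's outer-wall voxels in the slab normal to the local tangent — near
the carina a branch's cross-section is only part of the merged lumen and
any centroid is biased, but the outer-wall arc is an arc of the true tube
circle there, so the fitted centre is not. A slab-centroid fallback covers
degenerate fits, a running median removes single rogue nodes, and about one
radius is trimmed at tube caps where no full cross-section exists.

The bifurcation point is where straight lines fitted to the CCA and each
daughter centreline (excluding ~one diameter at the carina end and half a
radius at the far end) meet; the two daughter estimates are averaged, with
a carina-apex fallback (the ICA/ECA label interface nearest the CCA) when
the fits are near-parallel or inconsistent. Centreline points still inside
the overlap zone with another branch are dropped, and every branch is
attached to the common bifurcation point.

Per-point diameter is the equivalent-circle diameter 2√(A/π) of the
same-label voxel count in a one-voxel slab normal to the tangent — robust
for non-circular lumens. The branch mean excludes points within one
diameter of the bifurcation (cross-sections there cut several branches);
whether the reported diameters of any given study include the bulb region
is rarely stated, so the exclusion is a documented choice here. The
bifurcation angle is the angle between vectors from each daughter's point
nearest the bifurcation to the arc-length midpoint of that daughter's
centreline ("midpoint" by arc length, not index, for invariance to point
density). Across phantoms spanning diameters ~5–11 mm and angles 25–75°,
diameters recover within one voxel and the angle within 2°.

## Cohort statistics

Spearman rank correlations (midrank ties, two-sided large-sample p) with
pairwise-complete observations and at least 5 pairs; strength labels on the
conventional scale (boundaries 0.2/0.4/0.6/0.8, boundary values to the
higher bracket). Branch comparisons use Welch (unequal-variance) two-sample
t-tests at α = 0.05 — "two-sample t-test" is underspecified and Welch is
the safer default. No multiple-testing correction is applied by default,
matching common reporting in this literature; an adjustment helper exists.
Time-resolved correlations pool branch-mean-per-timeframe rows (one row per
bifurcation × branch × frame); pooling vertices instead would mix spatial
and temporal variation, and pooling only frame means would discard the
branch structure. The two carotids of one subject are treated as
independent observations, a simplification the row unit (bifurcation,
branch) makes explicit.

## Pipeline, sizes and determinism

The default pipeline simulates 10 bifurcations at 40 timeframes,
preprocesses (offset correction, up-sampling to 0.55 mm as float32),
extracts geometry, computes WSS and nwTKE, reduces to per-branch summaries
and builds the cohort tables; it completes in a few minutes on one CPU and
is bit-identical across reruns with the same seed (the manifest records
config hash and per-file checksums). Unknown config keys are rejected
before any stage runs. Tests use smaller cohorts (5 bifurcations, 8
frames) and the oracle phantoms described above; the acceptance script
reports the problem sizes it used alongside each number.

## Limitations

* Quasi-steady flow, rigid circular-tube geometry, and isotropic synthetic
  turbulence: the phantoms validate estimators, not physiology.
* No MR signal simulation — aliasing, phase wrapping, partial-volume signal
  mixing and concomitant-gradient effects are out of scope; IVSD is
  consumed as a given field, not estimated from signal magnitudes.
* The smoothing-spline WSS estimator carries the boundary-condition bias
  discussed above; comparisons across studies are meaningful mainly when
  acquisition resolution and probe settings match.
* Registration between morphology and velocity grids is assumed done
  (synthetic data are co-registered by construction).
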