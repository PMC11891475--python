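# Methods

This note documents the models, numerical choices, and defaults behind
`lvflow`, and what the synthetic phantoms do and do not establish about real
4D-flow data.

## Velocity-field model and interpolation

A dataset is a `(T, 3, nx, ny, nz)` array of velocities in cm/s on a regular
grid (spacing and origin in mm, voxel-centre addressing, right-handed world
frame) with strictly increasing phase times in ms and an RR interval
`cycle_length`.  Interpolation is trilinear in space and linear in time; the
cardiac cycle is treated as periodic, with the segment between the last
reconstructed phase and phase 0 spanning `cycle_length − phase_times[-1]`, so
sampling is continuous across the seam.  Positions outside the bounding box
of voxel centres raise an out-of-domain error rather than extrapolating:
extrapolated velocities are meaningless and the tracer treats them as trace
termination.  No interpolation scheme is canonical for 4D flow;
trilinear+linear is the common, monotone, cheapest choice and its error is
dwarfed by acquisition noise at clinical resolution.

Aliasing screening (`validate_field`) only reports the fraction of samples
with any component beyond Venc (default 150 cm/s) plus non-finite entries;
no unwrapping is attempted — inputs are assumed phase-corrected upstream.

## Geometry

* **Signed distance.**  Distances to the LV wall are taken from a Euclidean
  distance transform of the binary mask, negative inside, with a half-voxel
  shift toward the boundary so that surface points read |d| ≤ 0.5 voxel
  (the raw transform measures centre-to-centre distances and would bias all
  distances outward by half a voxel).  The map is computed once per mask and
  interpolated trilinearly; outside the mask grid it is +∞.
* **Valve planes** are oriented discs (tracked centre, forward-flow unit
  normal, in-plane radius) per cardiac phase, interpolated linearly and
  cyclically; interpolated normals are renormalised.  A disc is the minimal
  faithful model of a delineated annulus.
* **Rigid alignment** (cine → flow space) applies a given rotation +
  translation to points and normals; masks are resampled nearest-neighbour
  (labels preserved) and volumes recomputed.  Estimating the transform is
  out of scope — it is an input.
* **Seeding** places one particle at the world-frame centre of every
  end-diastolic voxel whose signed distance is ≤ −margin (default 2.5 mm,
  guarding against segmentation error at the endocardial border).

## Particle tracing

Classical RK4 with a 10 ms default step (configurable); velocities are
converted cm/s → mm/ms once inside the integrator.  Forward traces run from
end-diastole to end-systole (covering ejection); backward traces run from
end-diastole backward through diastole to the previous end-systole (covering
filling).  End-systole defaults to the closure of aortic forward flow read
off the aortic flux curve, with an explicit override.  If the step does not
divide the interval, the final partial step uses the remainder, so traces
end exactly at end-systole.

After each step, in order: (1) mitral-disc crossing, (2) aortic-disc
crossing — both tested on the straight step segment against the disc
interpolated at the segment mid-time, with a strict sign change of the
plane-normal distance and an in-plane radius bound; if one segment crosses
both discs the smaller interpolation parameter wins, mitral on ties —
then (3) the displacement stop (signed distance to the end-diastolic mask
> 3 cm).  Sub-step sampling failures terminate the trace as `left_domain`
at the pre-step position.  The whole tracer is vectorised over seeds and
bit-deterministic.

Measured convergence order on a field with a closed-form solution is 4.0
(the suite asserts 4.0 ± 0.3).

## Classification and quality

Origin = mitral iff the backward trace crossed the mitral disc; fate =
aortic iff the forward trace crossed the aortic disc; the four combinations
give DF/DEF/RI/RV.  Excluded are particles with either trace ending
`left_domain` or `displacement_exceeded` (no origin/fate is guessed for
them), and retained particles ending > 5 mm outside the end-systolic model
without valve involvement.  Fractions are over included particles (they sum
to 1); the excluded fraction is over all seeded particles.  The signed
mismatch DEF − RI is reported; its absolute value is gated strictly at 10 %
and the excluded fraction strictly at 20 %.  EF uses the end-diastolic mask
volume as denominator (recorded in the output metadata, since a cine-derived
EDV could differ).

## Haemodynamics

KE per voxel = ½ ρ |v|² V_voxel with ρ = 1060 kg/m³ (standard blood
density, configurable), reported in µJ.  Vorticity is the curl magnitude
from central differences on the full grid (one-sided at borders), in 1/s;
totals sum voxel magnitudes — a vector sum would cancel opposing rotation
and could not produce positive per-phase totals.  Both use the end-diastolic
endocardial mask at all three landmark phases unless per-phase masks are
supplied, and are indexed to EDV.

Flux curves sample the through-plane velocity on an in-plane raster of the
valve disc (raster spacing = ¼ of the smallest grid spacing, resolving the
disc rim sub-voxel) at every stored phase; net forward volume integrates
the positive part trapezoidally around the full cycle.  Peak-systole is the
aortic forward-flow maximum; end-systole is the interpolated end of the
contiguous aortic forward-flow run containing it; E-peak and A-peak are the
first and last local maxima of mitral forward flow after end-systole, the
A-peak being flagged undefined for monophasic inflow.

## Phantoms

### Channel

A straight duct (default 160 × 24 × 24 mm, 2 mm grid) with spatially uniform
plug flow u(t) x̂ — trivially divergence-free — built from Hann-lobe
waveforms: one systolic lobe and an E+A diastolic pair (65 % of filling in
the E-wave), scaled to prescribed systolic/diastolic displacements Ds, Dd
(defaults L/2).  A mitral disc closes the inlet, an aortic disc the outlet.
Particle motion is 1-D advection, so a seed at x₀ is ejected iff
x₀ > L − Ds and of mitral origin iff x₀ < Dd; ground-truth fractions are
interval lengths over the seeded span (the 2.5 mm seed margin is accounted
for; the duct is long relative to the margin so the truncation stays below
a percentage point).  Ground truth uses the displacement of the *sampled,
linearly interpolated* waveform — the quantity the tracer actually
integrates — evaluated by dense quadrature, independent of the RK4 path.

### Ellipsoidal LV

A half-ellipsoid cavity (base radius 34 mm, apex depth 54 mm, EDV ≈ 131 mL)
closed by a base plane carrying mitral and aortic discs (radius 13.5 mm,
centres ±15 mm).  Each disc drives a transvalvular jet defined by the
axisymmetric Stokes streamfunction ψ = Q(t)·Φ(ρ/R(z))/2π with the
Poiseuille profile Φ(u) = u²(2 − u²) for u < 1 (1 beyond) and jet radius
R(z) = R₀√(1 + (z/H)²), H = 10 mm.  This field is exactly divergence-free,
carries the full flux Q(t) through *every* jet cross-section — so mitral
and aortic net volumes equal the prescribed 70 mL stroke volume by
construction — and vanishes on the base plane outside its own disc, so
particles can only leave the cavity through a valve (measured excluded
fraction ≈ 1 %).  Equal mitral and aortic radii make the systolic and
diastolic transport columns congruent, so DEF/RI balance is a property of
the construction rather than of numerical cancellation; this is mildly
stylised (anatomically the mitral annulus is larger) but keeps the
conservation oracle sharp.  Peak jet velocities at the default waveforms are
≈ 1.0 m/s (mitral E) and ≈ 1.5 m/s (aortic), within the 150 cm/s Venc
convention for the stored field.  No closed form exists for per-seed fates;
the oracle labelling integrates the same field at a 1 ms step (10× finer
than the analysis default) — coarse/fine agreement is ≥ 95 % of seeds.

What the phantoms do **not** emulate: wall motion (the masks are static, so
particle-derived SV underestimates the flux-derived SV — ejected fluid
partly originates outside the seeded cavity), chamber anatomy, vortex
formation, k-space acquisition effects, and background-phase errors.
Passing tests therefore establish the correctness of the *analysis chain*
(integration, crossing detection, classification, flux integration,
statistics), not the physiological accuracy of any particular scan.

### Respiratory corruption

A non-gated scan averages data over the breathing cycle.  The model
replaces the field by the mean of itself rigidly displaced along a fixed
direction by heart displacements 0.6 × d_k, where d_k follows a
raised-cosine diaphragm trajectory with an end-expiratory plateau
(d(τ) = A((1 − cos 2πτ)/2)², amplitude A in diaphragm mm), sampled at 12
stratified breathing phases with state 0 anchored at end-expiration.  A
gating window w keeps only states with d_k ≤ w (window 0 reduces to the
clean reference state; no window averages everything).  The default
direction is 30° off the phantom long axis: the LV long axis is oblique to
the craniocaudal breathing motion, and a purely axial shift would be nearly
a symmetry of the jet fields.  Averaging acts in the image domain; k-space
simulation is deliberately out of scope — the mechanism of interest is the
blurring itself.  Only relative effects (monotone growth of |DEF − RI| with
amplitude; gated < ungated) are asserted, not absolute magnitudes.

## Statistics

Paired t-tests use the classical d̄/(s_d/√n) statistic (two-sided).  The
intraclass correlation is ICC(2,1) — two-way mixed effects, absolute
agreement, single measurement — computed from the ANOVA mean squares, with
the F test MSR/MSE for its p-value; the variant is recorded in every report
header because "ICC" alone is ambiguous.  The implementation is
cross-checked against `pingouin.intraclass_corr` (ICC(A,1)) to 1e-9 in the
test suite.  No multiple-testing correction is applied; each metric is
tested at α = 0.05.  The comparison stage optionally drops subjects whose
|DEF − RI| exceeds 10 % in both conditions before testing — the same
exclusion a quality-gated cohort analysis would apply.

## Problem sizes and tolerances

Default phantom runs use a 2 mm grid and 30 phases (~12 000 seeds for the
ellipsoid, ~6 000 for the duct); one full analysis takes a few seconds.
Channel recovery is asserted within 3 pp per component, flux conservation
within 3 %, the corruption contrast over 10 breathing realisations per
condition, and the null type-I error over 1000 replicates within ±0.02 of
α.  Degenerate inputs fail loudly: empty end-diastolic masks, zero seeds,
all-excluded analyses, zero-variance paired differences, monophasic inflow
(A-peak flagged), and valve discs leaving the grid all raise descriptive
errors rather than returning silent numbers.
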