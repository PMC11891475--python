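# lvflow

Left-ventricular 4D-flow analysis: four-component intracardiac particle
tracing, valve-plane flux quantification, kinetic-energy and vorticity
mapping, built-in data-quality gating, and paired two-condition comparison —
with synthetic flow phantoms whose particle fates are analytically known.

## Who this is for

Time-resolved three-directional phase-contrast MRI ("4D flow") measures the
blood velocity field **v**(x, t) throughout the cardiac cycle.  Releasing
massless virtual particles into that field and integrating their pathlines
splits the end-diastolic left-ventricular (LV) blood volume into the four
classical flow components:

| component | origin → fate |
|---|---|
| direct flow (DF) | in through the mitral valve → out through the aortic valve |
| delayed ejection flow (DEF) | resident at end-diastole → ejected in systole |
| retained inflow (RI) | in through the mitral valve → still in the LV at cycle end |
| residual volume (RV) | resident throughout |

`lvflow` implements this analysis for researchers who work with intracardiac
4D-flow data or study its error sources (respiratory motion, velocity noise,
integration step), and who need a testable, scriptable implementation rather
than a vendor black box.

## The method

* **Pathline integration.**  Particles are seeded at the centre of every
  voxel of the end-diastolic LV model that lies ≥ 2.5 mm inside the wall,
  then advected with classical fourth-order Runge–Kutta steps (default
  10 ms), forward from end-diastole through systole to end-systole and
  backward through diastole.  Sampling is trilinear in space, linear and
  cyclic in time.  A trace halts when it crosses a tracked valve disc,
  strays more than 3 cm outside the end-diastolic model, or leaves the
  imaged volume.
* **Classification.**  The backward trace fixes the particle's origin
  (mitral valve or LV), the forward trace its fate (aortic valve or
  retained), giving DF/DEF/RI/RV; particles with broken traces, or retained
  ones ending > 5 mm outside the end-systolic model, are excluded.  Stroke
  volume SV = (N_DF + N_DEF) · V_voxel, mitral inflow = (N_DF + N_RI) ·
  V_voxel, EF = SV/EDV.
* **Quality gates.**  In a normally functioning heart DEF and RI carry equal
  volumes, so `mismatch = DEF − RI` is a data-quality metric: an analysis
  passes iff |mismatch| < 10 % and the excluded-particle fraction < 20 %.
* **Haemodynamics.**  Per voxel, KE = ½ ρ |v|² V_voxel (ρ = 1060 kg/m³) and
  vorticity = |∇ × v|; totals over the LV are indexed to end-diastolic
  volume and evaluated at peak-systole, E-peak, and A-peak, which are
  identified from the mitral/aortic through-plane flux curves.
* **Statistics.**  Paired t-tests and ICC(2,1) (two-way mixed, absolute
  agreement, single measures) compare two scan conditions per metric at
  α = 0.05.
* **Phantoms.**  A plug-flow channel phantom with closed-form component
  fractions, and a half-ellipsoidal LV phantom driven by divergence-free
  transvalvular jet fields that carry an exactly prescribed stroke volume,
  plus a respiratory-blurring model (image-domain averaging over breathing
  states, with an optional navigator-style gating window) and Gaussian
  velocity noise.  See `docs/methods.md` for the constructions.

## Worked example

```bash
python examples/channel_components.py
```

```
duct 160 mm, systolic = diastolic displacement = 80 mm
component  estimated  ground truth
DF          0.013         0.000
DEF         0.494         0.500
RI          0.494         0.500
RV          0.000         0.000

excluded fraction: 0.0% (should be ~0: no noise, no wall leakage)
```

Half the duct is ejected each systole and refilled each diastole, so DEF and
RI must each hold half the included particles — the pipeline recovers both to
0.6 pp.  On the ellipsoidal phantom (`examples/lv_hemodynamics.py`) with a
70 mL prescribed stroke volume the measured valve volumes are

```
mitral net forward volume: 69.46 mL
aortic net forward volume: 69.44 mL
```

and `examples/respiratory_contrast.py` shows the |DEF − RI| quality metric
rising from 0.5 pp (clean field) to 3.6 pp under 15 mm respiratory blurring,
with a 6 mm gating window recovering most of the loss (1.6 pp).

Other entry points: `examples/paired_comparison.py` (two-condition report
with the |DEF−RI| > 10 % exclusion rule) and the `lvflow` CLI
(`lvflow simulate`, `lvflow run <config.yaml>`, `lvflow compare`).

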