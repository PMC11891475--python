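"""Four-component analysis on a plug-flow duct with closed-form truth.

Builds a straight-channel phantom in which every particle's fate is known
analytically (1-D advection), runs the full tracing + classification
pipeline, and prints the recovered flow-component fractions next to the
ground truth.  Agreement within a few percentage points demonstrates that
the tracer, the valve-crossing logic, and the classifier work together.
"""

from lvflow import PhantomSpec, TraceConfig, analyze_case, make_channel_phantom

spec = PhantomSpec(geometry="channel")
half = spec.length / 2
phantom = make_channel_phantom(
    PhantomSpec(geometry="channel", systolic_displacement=half,
                diastolic_displacement=half)
)
result = analyze_case(phantom.field, phantom.model, phantom.mitral,
                      phantom.aortic, TraceConfig())

print(f"duct {spec.length:.0f} mm, systolic = diastolic displacement = {half:.0f} mm")
print(f"{'component':<6} {'estimated':>10} {'ground truth':>13}")
for label in ("DF", "DEF", "RI", "RV"):
    print(f"{label:<6} {result.components.fractions[label]:>10.3f} "
          f"{phantom.ground_truth.fractions[label]:>13.3f}")
print(f"\nexcluded fraction: {result.components.excluded_fraction:.1%} "
      "(should be ~0: no noise, no wall leakage)")
print("With half-length displacements every ejected particle is replaced by "
      "inflow: DEF and RI are each half the cavity, DF and RV vanish.")
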