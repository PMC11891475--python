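"""Effect of respiratory blurring on the DEF/RI data-quality metric.

Corrupts the LV phantom's velocity field by averaging over displaced
breathing states (the mechanism by which a non-gated scan blurs the data),
with and without a 6 mm navigator-style gating window, and prints the
|DEF - RI| mismatch and excluded-particle fraction for each condition.
In a closed, conservative flow DEF and RI must balance, so any growth in
the mismatch is measurement error introduced by the corruption.
"""

import numpy as np

from lvflow import (
    PhantomSpec,
    RespiratoryCorruption,
    TraceConfig,
    analyze_case,
    apply_respiratory_corruption,
    make_lv_phantom,
)

N_SEEDS = 3  # breathing-pattern realisations per condition (demo size)

phantom = make_lv_phantom(PhantomSpec(geometry="ellipsoid"))
base = analyze_case(phantom.field, phantom.model, phantom.mitral,
                    phantom.aortic, TraceConfig())
print(f"{'condition':<28} {'|DEF-RI| (pp)':>14} {'excluded':>9}")
print(f"{'uncorrupted':<28} {abs(base.components.def_ri_mismatch) * 100:>14.2f} "
      f"{base.components.excluded_fraction:>9.1%}")

for label, window in (("15 mm, no gating", None), ("15 mm, 6 mm window", 6.0)):
    mm, ex = [], []
    for seed in range(N_SEEDS):
        cor = RespiratoryCorruption(amplitude=15.0, gating_window=window, rng_seed=seed)
        blurred = apply_respiratory_corruption(phantom.field, cor)
        r = analyze_case(blurred, phantom.model, phantom.mitral, phantom.aortic,
                         TraceConfig())
        mm.append(abs(r.components.def_ri_mismatch))
        ex.append(r.components.excluded_fraction)
    print(f"{label:<28} {np.mean(mm) * 100:>14.2f} {np.mean(ex):>9.1%}")

print("\nGating keeps only states near end-expiration, so the gated mismatch "
      "sits between the uncorrupted and the fully blurred value.")
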