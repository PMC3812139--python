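"""Preprocess the recordings and apply the trial-selection cascade.

Blinks are reconstructed by cubic-spline interpolation, trials are epoched
and baseline-normalized, and the per-experiment discard rules run in their
fixed order (gaze error -> timeout -> RT outliers -> pupil outliers ->
gaze-bias pairing).  Writes the per-rule discard fractions to results/.
"""

import json

from common import RESULTS, bundle

for exp in ("exp1", "exp2"):
    b = bundle(exp)
    sel = b["selection"]
    payload = {"preprocessing": b["preprocessing"], "selection": sel}
    out = RESULTS / f"selection_{exp}.json"
    out.write_text(json.dumps(payload, indent=1))
    fracs = ", ".join(f"{k} {100 * v:.1f}%" for k, v in sel["fractions"].items())
    print(f"{exp}: {sel['surviving']}/{sel['total']} traces retained "
          f"({fracs}); blinks repaired: {b['preprocessing']['blinks_repaired']}")
    print(f"  mean horizontal gaze bias of retained trials: "
          f"{sel['mean_retained_bias']:+.4f} deg")
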