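"""Relate the pupil-size modulation to behavioral cueing effects.

Speeded design: rank-order bin pairing (fastest valid vs slowest invalid
quartiles and so on), bin-level modulation areas, and a mixed model of
modulation on cueing effect with a participant random intercept.
Accuracy design: per-participant accuracy cueing effect and a
between-subject Pearson correlation with the modulation.  Cohen's d of
each per-participant effect against zero quantifies effect sizes.
"""

import json

import pandas as pd

from common import RESULTS, bundle

out = {}

b1 = bundle("exp1")
beh1 = b1["behavior"]
pd.DataFrame(beh1["bins"]).to_csv(RESULTS / "bin_table_exp1.csv", index=False)
out["exp1"] = {
    "rt_valid_ms": round(beh1["rt_valid_mean_ms"], 1),
    "rt_invalid_ms": round(beh1["rt_invalid_mean_ms"], 1),
    "modulation_model": beh1["model"],
    "effect_sizes": beh1["effect_sizes"],
}
m = beh1["model"]
print(f"exp1: RT valid {out['exp1']['rt_valid_ms']:.0f} ms, "
      f"invalid {out['exp1']['rt_invalid_ms']:.0f} ms")
print(f"  modulation ~ cueing effect ({m['method']}): slope {m['slope']:.3g}, "
      f"t = {m['t_value']:.2f}, p = {m['p_value']:.4g} over {m['n_bins']} bins")
print(f"  Cohen's d vs 0: behavior {beh1['effect_sizes']['d_behavior']:.2f}, "
      f"pupil {beh1['effect_sizes']['d_pupil']:.2f}")

b2 = bundle("exp2")
beh2 = b2["behavior"]
out["exp2"] = {
    "accuracy_valid_pct": round(beh2["accuracy_valid_pct"], 1),
    "accuracy_invalid_pct": round(beh2["accuracy_invalid_pct"], 1),
    "correlation": beh2["correlation"],
    "effect_sizes": beh2["effect_sizes"],
}
c = beh2["correlation"]
print(f"exp2: accuracy valid {out['exp2']['accuracy_valid_pct']:.1f}%, "
      f"invalid {out['exp2']['accuracy_invalid_pct']:.1f}%")
print(f"  between-subject correlation: r = {c['r']:.2f}, p = {c['p']:.4f} "
      f"(n = {c['n']})")
print(f"  Cohen's d vs 0: behavior {beh2['effect_sizes']['d_behavior']:.2f}, "
      f"pupil {beh2['effect_sizes']['d_pupil']:.2f}")

(RESULTS / "behavior_link.json").write_text(json.dumps(out, indent=1))
print(f"summary -> {RESULTS / 'behavior_link.json'}")
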