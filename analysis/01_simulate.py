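"""Simulate the two cueing experiments and archive the raw datasets.

Generates a speeded-RT design (visual cue, 75% validity, 15 x 160 trials)
and an unspeeded accuracy design (auditory cue, 80% validity, staircase,
15 x 240 trials) with known ground truth, writes the sample streams and
trial tables under scratch/ (they are bulky), and a compact design
summary under results/.
"""

import json

from common import RESULTS, SCRATCH, config
from plrmod import io as pio
from plrmod.synth import exp1_config, exp2_config, simulate_experiment

summary = {}
for exp in ("exp1", "exp2"):
    cfg = config(exp)
    maker = exp1_config if exp == "exp1" else exp2_config
    sim = simulate_experiment(
        maker(n_participants=cfg.n_participants, n_trials=cfg.n_trials,
              sampling_rate=cfg.sampling_rate, seed=cfg.seed)
    )
    out = SCRATCH / f"data_{exp}"
    out.mkdir(parents=True, exist_ok=True)
    pio.write_samples_csv(sim.samples, out / "samples.csv")
    pio.write_trials_csv(sim.trials, out / "trials.csv")
    pio.write_ground_truth(sim.ground_truth, out / "ground_truth.json")
    tt = sim.trials
    summary[exp] = {
        "participants": int(tt.participant.nunique()),
        "trials": len(tt),
        "valid_fraction": round(float((tt.validity == "valid").mean()), 3),
        "mean_soa_ms": round(float(tt.soa_ms.mean()), 1),
        "timeouts": int(tt.timeout.sum()),
    }
    print(f"{exp}: {summary[exp]['trials']} trials, "
          f"{100 * summary[exp]['valid_fraction']:.1f}% validly cued, "
          f"mean cue-target interval {summary[exp]['mean_soa_ms']:.0f} ms "
          f"-> {out}")

RESULTS.mkdir(exist_ok=True)
(RESULTS / "simulation_summary.json").write_text(json.dumps(summary, indent=1))
print(f"design summary -> {RESULTS / 'simulation_summary.json'}")
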