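"""Shared settings for the numbered analysis scripts.

All scripts analyze the same pair of simulated experiments, reproduced
deterministically from one seed, at a 250 Hz analysis grid (the run
criterion for divergence rescales to 50 consecutive samples).  Small
summary tables go to results/, bulky intermediates to scratch/.
"""

from pathlib import Path

from plrmod.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1
RATE = 250.0


def config(experiment: str) -> PipelineConfig:
    n_trials = 160 if experiment == "exp1" else 240
    return PipelineConfig(
        experiment=experiment, n_participants=15, n_trials=n_trials,
        sampling_rate=RATE, seed=SEED if experiment == "exp1" else SEED + 1,
    )


def bundle(experiment: str) -> dict:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return run_pipeline(config(experiment))
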