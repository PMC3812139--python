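"""Reading and writing the pipeline's tidy text formats.

Samples: long CSV with columns (participant, trial, t_ms, pupil_area,
gaze_x_deg, gaze_y_deg); missing pupil during blinks is an empty field.
Trial table: one row per trial with design factors and behavioral
outcomes.  Ground truth: JSON sidecar with the generating parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SampleSeries

SAMPLE_COLUMNS = ["participant", "trial", "t_ms", "pupil_area", "gaze_x_deg", "gaze_y_deg"]
TRIAL_COLUMNS = [
    "participant", "trial", "experiment", "cue_side", "target_side", "validity",
    "bright_side", "attend_condition", "soa_ms", "rt_ms", "correct", "snr_percent",
]


def write_samples_csv(samples: dict[tuple[int, int], SampleSeries], path) -> None:
    parts = []
    for (p, tr), series in sorted(samples.items()):
        parts.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "trial": tr,
                    "t_ms": series.t,
                    "pupil_area": series.pupil,
                    "gaze_x_deg": series.gaze_x,
                    "gaze_y_deg": series.gaze_y,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, na_rep="")


def read_samples_csv(path) -> dict[tuple[int, int], SampleSeries]:
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"samples file {path!r} lacks columns {sorted(missing)}")
    out: dict[tuple[int, int], SampleSeries] = {}
    for (p, tr), g in df.groupby(["participant", "trial"], sort=True):
        out[(int(p), int(tr))] = SampleSeries(
            t=g.t_ms.to_numpy(float),
            pupil=g.pupil_area.to_numpy(float),
            gaze_x=g.gaze_x_deg.to_numpy(float),
            gaze_y=g.gaze_y_deg.to_numpy(float),
        )
    return out


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials[cols].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns) - {"snr_percent"}
    if missing:
        raise ValueError(f"trial table {path!r} lacks columns {sorted(missing)}")
    return df


def write_ground_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
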