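"""Trial selection: gaze, timeout and outlier filters, gaze-bias pairing.

Filters are applied in a fixed, documented order — gaze error, timeout,
RT outliers, pupil-size outliers, gaze-bias pairing — and every discarded
trial carries exactly one primary reason code, so the per-rule discard
fractions in the :class:`SelectionReport` are interpretable.

The pairing control removes directional bias in fixational eye movements:
within each participant and attend condition, every trial must be paired
with another whose mean horizontal gaze bias during the cue-target epoch
is opposite in sign but equal in magnitude to within a tolerance
(default 0.14 deg); unpaired trials are discarded.  For opposite-sign
pairs the conditions ``|b1 + b2| < tol`` and ``||b1| - |b2|| < tol`` are
the same, so a single criterion implements both readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialRecord",
    "SelectionReport",
    "filter_gaze",
    "filter_timeouts",
    "filter_rt_outliers",
    "filter_pupil_outliers",
    "pair_gaze_bias",
    "apply_selection",
]

RULE_ORDER = ("gaze", "timeout", "rt_outlier", "pupil_outlier", "unpaired")


@dataclass
class TrialRecord:
    """Per-trial design factors and summary measures used for selection."""

    participant: int
    trial: int
    validity: str  # "valid" | "invalid"
    attend_condition: str  # "bright" | "dark"
    rt: float  # ms
    correct: bool
    mean_pupil: float  # trial-average pupil area, arbitrary units
    gaze_bias: float  # mean horizontal gaze during cue-target epoch, deg
    max_gaze_dev: float  # max radial gaze deviation, deg
    max_horiz_dev: float = np.nan  # max |horizontal| deviation, deg
    timeout: bool = False


@dataclass
class SelectionReport:
    """Counts and fractions discarded per rule, in application order."""

    total: int
    discarded: dict[str, int] = field(default_factory=dict)
    rule_order: tuple[str, ...] = RULE_ORDER
    mean_retained_bias: float = np.nan

    @property
    def surviving(self) -> int:
        return self.total - sum(self.discarded.values())

    def fractions(self) -> dict[str, float]:
        return {k: v / self.total if self.total else 0.0 for k, v in self.discarded.items()}

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "surviving": self.surviving,
            "discarded": dict(self.discarded),
            "fractions": self.fractions(),
            "rule_order": list(self.rule_order),
            "mean_retained_bias": self.mean_retained_bias,
        }


def filter_gaze(
    trials: list[TrialRecord],
    mode: str = "any_sample_radius",
    limit_deg: float = 2.0,
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Discard trials with excessive gaze deviation.

    ``any_sample_radius`` (experiment 1): discard when any sample deviates
    more than ``limit_deg`` radially from fixation.  ``horizontal_band``
    (experiment 2, default limit 2.8 deg): discard when the horizontal
    deviation exceeds the maximum displacement of the central gray band.
    Trials with no usable gaze stream (NaN deviation) are discarded.
    """
    kept, discarded = [], []
    for trial in trials:
        dev = trial.max_gaze_dev if mode == "any_sample_radius" else trial.max_horiz_dev
        if mode not in ("any_sample_radius", "horizontal_band"):
            raise ValueError(f"unknown gaze filter mode {mode!r}")
        if np.isnan(dev) or dev > limit_deg:
            discarded.append(trial)
        else:
            kept.append(trial)
    return kept, discarded


def filter_timeouts(
    trials: list[TrialRecord], limit_ms: float = 5000.0
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Discard trials without a response within ``limit_ms``."""
    kept = [t for t in trials if not t.timeout and t.rt <= limit_ms]
    discarded = [t for t in trials if t.timeout or t.rt > limit_ms]
    return kept, discarded


def _sd_filter(trials, attr: str, n_sd: float):
    """Single-pass per-participant mean +/- n_sd * SD bound on ``attr``.

    The mean and sample SD include the candidate outlier itself (no
    iterative trimming); participants with SD = 0 or fewer than 3 trials
    discard nothing.
    """
    by_p: dict[int, list[TrialRecord]] = {}
    for t in trials:
        by_p.setdefault(t.participant, []).append(t)
    kept, discarded = [], []
    for group in by_p.values():
        vals = np.array([getattr(t, attr) for t in group], dtype=float)
        if len(group) < 3:
            kept.extend(group)
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            kept.extend(group)
            continue
        for t, v in zip(group, vals):
            (kept if abs(v - mean) <= n_sd * sd else discarded).append(t)
    order = {(t.participant, t.trial): i for i, t in enumerate(trials)}
    key = lambda t: order[(t.participant, t.trial)]
    return sorted(kept, key=key), sorted(discarded, key=key)


def filter_rt_outliers(
    trials: list[TrialRecord], n_sd: float = 2.5
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Discard trials whose RT is beyond n_sd SDs of the participant mean."""
    return _sd_filter(trials, "rt", n_sd)


def filter_pupil_outliers(
    trials: list[TrialRecord], n_sd: float = 2.5
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Discard trials whose trial-average pupil area is a per-participant outlier."""
    return _sd_filter(trials, "mean_pupil", n_sd)


def _match_magnitudes(
    pos: list[TrialRecord], neg: list[TrialRecord], tolerance: float
) -> list[tuple[TrialRecord, TrialRecord]]:
    """Maximum-cardinality pairing of opposite-sign biases within tolerance.

    Both sides are sorted by bias magnitude and swept with two pointers:
    if the current magnitudes differ by less than ``tolerance`` they are
    paired, otherwise the pointer at the smaller magnitude advances.  For
    this interval-compatibility structure the sweep attains the maximum
    matching (each element's compatible partners form a contiguous run in
    the sorted other side).
    """
    pos = sorted(pos, key=lambda t: (abs(t.gaze_bias), t.trial))
    neg = sorted(neg, key=lambda t: (abs(t.gaze_bias), t.trial))
    pairs = []
    i = j = 0
    while i < len(pos) and j < len(neg):
        a, b = abs(pos[i].gaze_bias), abs(neg[j].gaze_bias)
        if abs(a - b) < tolerance:
            pairs.append((pos[i], neg[j]))
            i += 1
            j += 1
        elif a < b:
            i += 1
        else:
            j += 1
    return pairs


def pair_gaze_bias(
    trials: list[TrialRecord],
    tolerance: float = 0.14,
    group_by_condition: bool = True,
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Pair trials with opposite but approximately equal gaze bias.

    Pairing is performed within participant (and, by default, within
    attend condition, preserving the contrast the control protects);
    trials that cannot be paired are discarded.  Returns (retained,
    discarded); retained trials come in pairs whose biases cancel to
    within ``tolerance``.
    """
    groups: dict[tuple, list[TrialRecord]] = {}
    for t in trials:
        key = (t.participant, t.attend_condition) if group_by_condition else (t.participant,)
        groups.setdefault(key, []).append(t)
    kept, discarded = [], []
    for group in groups.values():
        pos = [t for t in group if t.gaze_bias >= 0]
        neg = [t for t in group if t.gaze_bias < 0]
        pairs = _match_magnitudes(pos, neg, tolerance)
        matched = {id(t) for pair in pairs for t in pair}
        kept.extend(t for t in group if id(t) in matched)
        discarded.extend(t for t in group if id(t) not in matched)
    order = {(t.participant, t.trial): i for i, t in enumerate(trials)}
    key = lambda t: order[(t.participant, t.trial)]
    return sorted(kept, key=key), sorted(discarded, key=key)


def apply_selection(
    trials: list[TrialRecord],
    experiment: str = "exp1",
    gaze_limit_deg: float | None = None,
    rt_sd: float = 2.5,
    pupil_sd: float = 2.5,
    timeout_ms: float = 5000.0,
    pairing_tolerance: float = 0.14,
    enable: dict[str, bool] | None = None,
) -> tuple[list[TrialRecord], SelectionReport]:
    """Run the full selection cascade for one experiment profile.

    Experiment 1 (speeded, visual cue): radial 2 deg gaze filter, RT
    outliers, pupil outliers, gaze-bias pairing.  Experiment 2 (unspeeded,
    gaze-contingent band): horizontal 2.8 deg filter, 5000 ms timeout,
    pupil outliers; fixational bias was controlled online, so no pairing.
    Individual rules can be switched off via ``enable``.
    """
    enable = enable or {}
    report = SelectionReport(total=len(trials))
    current = list(trials)

    def on(rule: str, default: bool = True) -> bool:
        return enable.get(rule, default)

    if experiment == "exp1":
        if on("gaze"):
            current, d = filter_gaze(current, "any_sample_radius", gaze_limit_deg or 2.0)
            report.discarded["gaze"] = len(d)
        if on("rt_outlier"):
            current, d = filter_rt_outliers(current, rt_sd)
            report.discarded["rt_outlier"] = len(d)
        if on("pupil_outlier"):
            current, d = filter_pupil_outliers(current, pupil_sd)
            report.discarded["pupil_outlier"] = len(d)
        if on("pairing"):
            current, d = pair_gaze_bias(current, pairing_tolerance)
            report.discarded["unpaired"] = len(d)
    elif experiment == "exp2":
        if on("gaze"):
            current, d = filter_gaze(current, "horizontal_band", gaze_limit_deg or 2.8)
            report.discarded["gaze"] = len(d)
        if on("timeout"):
            current, d = filter_timeouts(current, timeout_ms)
            report.discarded["timeout"] = len(d)
        if on("pupil_outlier"):
            current, d = filter_pupil_outliers(current, pupil_sd)
            report.discarded["pupil_outlier"] = len(d)
    else:
        raise ValueError(f"unknown experiment profile {experiment!r}")

    if current:
        report.mean_retained_bias = float(np.mean([t.gaze_bias for t in current]))
    return current, report
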