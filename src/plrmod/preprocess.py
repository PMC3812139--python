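"""Pupil-trace preprocessing: blink reconstruction, epoching, normalization.

A raw recording is a uniformly sampled stream of time (ms), pupil area
(arbitrary units, missing during blinks) and gaze position (degrees from
display center).  Preprocessing turns it into baseline-normalized traces
aligned to the cue and to the target:

* blinks are detected as runs of missing samples, widened by a shoulder
  margin to swallow the partial-occlusion ramps on either side, and
  reconstructed with cubic-spline interpolation through four control
  samples flanking the gap;
* each trial is cut into three epochs — a 100 ms pre-cue baseline, the
  cue-target epoch and the target-response epoch — and pupil area is
  expressed as a fraction of the mean baseline area;
* no other smoothing is applied anywhere in the pipeline; the only
  smoothing-like operation is the 50 ms central-difference window used by
  the constriction-latency velocity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SampleSeries",
    "EpochedTrace",
    "BlinkRepair",
    "UnusableTrialError",
    "InvalidTrialError",
    "detect_blinks",
    "interpolate_blinks",
    "segment_and_normalize",
    "constriction_latency",
    "read_asc",
]


class UnusableTrialError(ValueError):
    """The recording cannot be preprocessed at all (e.g. fully missing)."""


class InvalidTrialError(ValueError):
    """The trial violates an epoching precondition (e.g. bad baseline)."""


@dataclass
class SampleSeries:
    """One trial's uniformly sampled eye-tracking streams.

    ``t`` is in milliseconds and must increase in uniform steps; ``pupil``
    is pupil *area* in arbitrary units with NaN marking missing samples
    (blinks); gaze coordinates are in degrees from the display center.
    """

    t: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        if not (len(self.t) == len(self.pupil) == len(self.gaze_x) == len(self.gaze_y)):
            raise ValueError("all sample streams must have equal length")
        if len(self.t) < 2:
            raise ValueError("a sample series needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6):
            raise ValueError("t must be strictly increasing with a uniform step")

    @property
    def dt(self) -> float:
        """Sampling step in ms."""
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class EpochedTrace:
    """Baseline-normalized pupil trace aligned to an epoch-defining event.

    ``t_rel`` is ms from the event (cue onset or target onset); windows are
    half-open ``[start, end)``.  ``pupil_norm`` is pupil area divided by the
    mean area over the 100 ms pre-cue baseline, so it averages ~1 during the
    baseline epoch.
    """

    epoch: str  # "baseline" | "cue_target" | "target_response"
    t_rel: np.ndarray
    pupil_norm: np.ndarray
    interpolated: np.ndarray | None = None  # bool mask, True where reconstructed

    @property
    def dt(self) -> float:
        return float(self.t_rel[1] - self.t_rel[0])


@dataclass
class BlinkRepair:
    """Record of one reconstructed interval."""

    start_ms: float
    end_ms: float
    method: str  # "cubic_spline" | "linear_edge"


def detect_blinks(
    series: SampleSeries,
    min_duration_ms: float = 0.0,
    margin_ms: float = 50.0,
) -> list[tuple[float, float]]:
    """Find blink intervals as maximal runs of missing pupil samples.

    Each run at least ``min_duration_ms`` long is widened by ``margin_ms``
    on both sides (to cover the eyelid-occlusion shoulders) and overlapping
    widened intervals are merged.  Returns sorted, non-overlapping
    ``(start_ms, end_ms)`` pairs, clipped to the recording.
    """
    missing = np.isnan(series.pupil)
    if missing.all():
        raise UnusableTrialError("pupil trace is entirely missing")
    if not missing.any():
        return []
    # edges of missing runs
    padded = np.concatenate(([False], missing, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
    intervals = []
    for s, e in zip(starts, ends):
        dur = series.t[e] - series.t[s] + series.dt
        if dur < min_duration_ms:
            continue
        intervals.append(
            (
                max(series.t[s] - margin_ms, series.t[0]),
                min(series.t[e] + margin_ms, series.t[-1]),
            )
        )
    # merge overlapping / touching intervals
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interpolate_blinks(
    series: SampleSeries,
    blinks: list[tuple[float, float]],
    margin_ms: float = 50.0,
) -> tuple[SampleSeries, list[BlinkRepair]]:
    """Reconstruct pupil area across blink intervals by cubic-spline fill.

    For a blink ``[s, e]`` the spline passes through the four control
    samples nearest to ``s - 2*margin``, ``s - margin``, ``e + margin`` and
    ``e + 2*margin``; samples strictly inside ``(s - margin, e + margin)``
    are replaced by the spline, everything else is bit-identical to the
    input.  A blink too close to a trace edge to place all four control
    points falls back to linear fill from the two nearest valid samples
    and is flagged ``linear_edge``.
    """
    pupil = series.pupil.copy()
    repairs: list[BlinkRepair] = []
    t = series.t
    for s, e in blinks:
        ctrl_t = np.array(
            [s - 2 * margin_ms, s - margin_ms, e + margin_ms, e + 2 * margin_ms]
        )
        idx = np.clip(np.round((ctrl_t - t[0]) / series.dt).astype(int), 0, len(t) - 1)
        inside = (t > s - margin_ms) & (t < e + margin_ms)
        if (
            len(np.unique(idx)) == 4
            and not np.any(np.isnan(pupil[idx]))
            and ctrl_t[0] >= t[0]
            and ctrl_t[-1] <= t[-1]
        ):
            spline = CubicSpline(t[idx], pupil[idx])  # not-a-knot: a single cubic
            pupil[inside] = spline(t[inside])
            repairs.append(BlinkRepair(s, e, "cubic_spline"))
        else:
            # edge blink: linear fill from nearest valid neighbours
            valid = ~np.isnan(pupil) & ~inside
            if valid.sum() < 2:
                raise UnusableTrialError("not enough valid samples to repair blink")
            pupil[inside] = np.interp(t[inside], t[valid], pupil[valid])
            repairs.append(BlinkRepair(s, e, "linear_edge"))
    out = replace(series, pupil=pupil)
    return out, repairs


def _window(series: SampleSeries, start_ms: float, end_ms: float) -> np.ndarray:
    """Index mask for the half-open window [start_ms, end_ms)."""
    return (series.t >= start_ms) & (series.t < end_ms)


def segment_and_normalize(
    series: SampleSeries,
    cue_onset_ms: float,
    target_onset_ms: float,
    response_time_ms: float,
    baseline_ms: float = 100.0,
    interpolated_mask: np.ndarray | None = None,
) -> dict[str, EpochedTrace]:
    """Cut a trial into baseline / cue-target / target-response epochs.

    The baseline epoch is the ``baseline_ms`` window ending at cue onset;
    its mean pupil area is the normalization divisor for the whole trial.
    The cue-target epoch runs from cue to target onset, the target-response
    epoch from target onset to ``response_time_ms`` after it.  Raises
    :class:`InvalidTrialError` when the baseline is non-positive or fully
    reconstructed from blinks.
    """
    if cue_onset_ms - baseline_ms < series.t[0]:
        raise InvalidTrialError("trace does not cover the baseline window")
    if target_onset_ms <= cue_onset_ms:
        raise InvalidTrialError("target onset must follow cue onset")
    base = _window(series, cue_onset_ms - baseline_ms, cue_onset_ms)
    base_vals = series.pupil[base]
    if np.any(np.isnan(base_vals)):
        raise InvalidTrialError("baseline contains missing samples")
    baseline_mean = float(np.mean(base_vals))
    if baseline_mean <= 0:
        raise InvalidTrialError("baseline mean pupil area is non-positive")
    if interpolated_mask is not None and bool(np.all(interpolated_mask[base])):
        raise InvalidTrialError("baseline is fully interpolated")

    def _epoch(name: str, start: float, end: float, zero: float) -> EpochedTrace:
        m = _window(series, start, end)
        interp = interpolated_mask[m] if interpolated_mask is not None else None
        return EpochedTrace(
            epoch=name,
            t_rel=series.t[m] - zero,
            pupil_norm=series.pupil[m] / baseline_mean,
            interpolated=interp,
        )

    end_ms = min(target_onset_ms + response_time_ms, series.t[-1] + series.dt)
    return {
        "baseline": _epoch("baseline", cue_onset_ms - baseline_ms, cue_onset_ms, cue_onset_ms),
        "cue_target": _epoch("cue_target", cue_onset_ms, target_onset_ms, cue_onset_ms),
        "target_response": _epoch("target_response", target_onset_ms, end_ms, target_onset_ms),
    }


def constriction_latency(
    trace: EpochedTrace,
    velocity_threshold: float = 0.5,
    window_ms: float = 50.0,
) -> float | None:
    """Latency of pupil constriction by a velocity criterion.

    Velocity is the central finite difference of the normalized trace over
    a ``window_ms`` window: ``v(t) = (x(t + w/2) - x(t - w/2)) / w`` in
    normalized size per second.  Returns the first ``t_rel`` (ms) at which
    ``v <= -velocity_threshold`` — constriction at or above the criterion
    rate — or None if the criterion is never met or the epoch is shorter
    than the velocity window.
    """
    dt = trace.dt
    half = max(int(round(window_ms / 2.0 / dt)), 1)
    x = trace.pupil_norm
    if len(x) <= 2 * half:
        return None
    v = (x[2 * half:] - x[:-2 * half]) / (2 * half * dt / 1000.0)
    hits = np.flatnonzero(v <= -velocity_threshold)
    if len(hits) == 0:
        return None
    return float(trace.t_rel[hits[0] + half])


def read_asc(path, missing_values=(".", "0", "0.0")) -> SampleSeries:
    """Read a minimal EyeLink-ASC-like text dialect into a SampleSeries.

    Accepts whitespace-separated sample lines ``t  x  y  pupil`` (gaze in
    degrees, pupil area in arbitrary units); non-numeric or zero pupil
    fields are treated as missing.  Lines that do not start with a numeric
    timestamp (``MSG``, ``SFIX`` ...) are skipped.
    """
    t, gx, gy, pupil = [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                continue
            try:
                ts = float(parts[0])
            except ValueError:
                continue
            t.append(ts)
            gx.append(_parse_field(parts[1], missing_values))
            gy.append(_parse_field(parts[2], missing_values))
            pupil.append(_parse_field(parts[3], missing_values))
    if not t:
        raise UnusableTrialError(f"no sample lines found in {path!r}")
    return SampleSeries(
        t=np.array(t), pupil=np.array(pupil), gaze_x=np.array(gx), gaze_y=np.array(gy)
    )


def _parse_field(token: str, missing_values) -> float:
    if token in missing_values:
        return np.nan
    try:
        return float(token)
    except ValueError:
        return np.nan
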