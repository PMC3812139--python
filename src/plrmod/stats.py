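"""Condition-mean traces, the modulation-area statistic and divergence onset.

The central quantity is the signed area between the attend-dark and the
attend-bright mean pupil traces over the 1000-2000 ms window of the
cue-target epoch, in baseline-normalized size x seconds: positive when the
pupil is larger while attending the dark side (the predicted direction of
an attentional modulation of the pupillary light response), with stretches
where the bright trace lies above counted as negative surface.

Divergence onset is the first time point opening a run of at least 200 ms
of consecutive pointwise significance (p < .05) for the condition effect;
the run criterion is re-expressed in samples at the actual sampling rate.
Because trial epochs vary in length (jittered cue-target interval,
variable response times), pointwise means are taken over the trials still
extant at each time point, so trial counts are non-increasing toward the
right edge of the traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .preprocess import EpochedTrace

__all__ = [
    "ConditionTraces",
    "ModulationResult",
    "DivergenceResult",
    "condition_traces",
    "participant_condition_means",
    "modulation_area",
    "pointwise_condition_test",
    "divergence_onset",
]


@dataclass
class ConditionTraces:
    """Pointwise mean pupil traces per attend condition on a shared grid."""

    t_rel: np.ndarray  # ms
    mean_dark: np.ndarray
    mean_bright: np.ndarray
    n_dark: np.ndarray
    n_bright: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t_rel[1] - self.t_rel[0])


@dataclass
class ModulationResult:
    """Signed area between condition traces over a fixed window."""

    area: float  # pupil_norm x seconds
    window: tuple[float, float]
    n_trials: int


@dataclass
class DivergenceResult:
    """Onset of sustained pointwise divergence between conditions."""

    onset_ms: float | None
    p_values: np.ndarray
    t_rel: np.ndarray
    run_samples: int
    alpha: float
    method: str = "participant_means_t"


def _stack(traces: list[EpochedTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length epochs into a NaN-padded matrix on a shared grid."""
    if not traces:
        raise ValueError("no traces to stack")
    dt = traces[0].dt
    for tr in traces:
        if not np.isclose(tr.dt, dt):
            raise ValueError("traces must share a sampling step")
        if not np.isclose(tr.t_rel[0], traces[0].t_rel[0]):
            raise ValueError("traces must share their epoch origin")
    n = max(len(tr.t_rel) for tr in traces)
    grid = traces[0].t_rel[0] + dt * np.arange(n)
    mat = np.full((len(traces), n), np.nan)
    for i, tr in enumerate(traces):
        mat[i, : len(tr.pupil_norm)] = tr.pupil_norm
    return grid, mat


def condition_traces(
    dark: list[EpochedTrace], bright: list[EpochedTrace]
) -> ConditionTraces:
    """Pointwise condition means over the trials extant at each time point.

    No interpolation or extension beyond a trial's end: a trial simply
    stops contributing once its epoch ends, so ``n_dark``/``n_bright``
    step down at each trial's last sample.
    """
    if not dark:
        raise ValueError("attend-dark condition is empty")
    if not bright:
        raise ValueError("attend-bright condition is empty")
    gd, md = _stack(dark)
    gb, mb = _stack(bright)
    n = max(len(gd), len(gb))
    dt = gd[1] - gd[0]
    grid = gd[0] + dt * np.arange(n)

    def pad(mat, width):
        out = np.full((mat.shape[0], width), np.nan)
        out[:, : mat.shape[1]] = mat
        return out

    md, mb = pad(md, n), pad(mb, n)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ConditionTraces(
            t_rel=grid,
            mean_dark=np.nanmean(md, axis=0),
            mean_bright=np.nanmean(mb, axis=0),
            n_dark=np.sum(~np.isnan(md), axis=0),
            n_bright=np.sum(~np.isnan(mb), axis=0),
        )


def modulation_area(
    traces: ConditionTraces, window: tuple[float, float] = (1000.0, 2000.0)
) -> ModulationResult:
    """Signed area between the dark and bright mean traces over ``window``.

    Trapezoidal integral of ``mean_dark - mean_bright`` in units of
    normalized pupil size x seconds; exact for piecewise-linear traces.
    Raises if either trace does not cover the full window.
    """
    lo, hi = window
    m = (traces.t_rel >= lo) & (traces.t_rel <= hi)
    covered = m & (traces.n_dark > 0) & (traces.n_bright > 0)
    t_cov = traces.t_rel[(traces.n_dark > 0) & (traces.n_bright > 0)]
    span_ok = len(t_cov) > 0 and t_cov[0] <= lo and t_cov[-1] + traces.dt > hi
    if not m.any() or not covered[m].all() or not span_ok:
        bounds = (float(t_cov[0]), float(t_cov[-1])) if len(t_cov) else (np.nan, np.nan)
        raise ValueError(
            f"window {window} not fully covered by both conditions (coverage {bounds})"
        )
    diff = traces.mean_dark[m] - traces.mean_bright[m]
    area = float(np.trapezoid(diff, traces.t_rel[m] / 1000.0))
    n_trials = int(traces.n_dark[m][0] + traces.n_bright[m][0])
    return ModulationResult(area=area, window=(lo, hi), n_trials=n_trials)


def participant_condition_means(
    traces_by_participant: dict[int, dict[str, list[EpochedTrace]]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-participant condition mean traces on a common grid.

    Returns ``(grid_ms, dark, bright)`` where ``dark``/``bright`` are
    ``(n_participants, n_timepoints)`` matrices, NaN where a participant
    has no extant trial.
    """
    grids, darks, brights = [], [], []
    for conds in traces_by_participant.values():
        ct = condition_traces(conds["dark"], conds["bright"])
        grids.append(ct.t_rel)
        darks.append(np.where(ct.n_dark > 0, ct.mean_dark, np.nan))
        brights.append(np.where(ct.n_bright > 0, ct.mean_bright, np.nan))
    n = max(len(g) for g in grids)
    dt = grids[0][1] - grids[0][0]
    grid = grids[0][0] + dt * np.arange(n)
    dark = np.full((len(darks), n), np.nan)
    bright = np.full_like(dark, np.nan)
    for i, (d, b) in enumerate(zip(darks, brights)):
        dark[i, : len(d)] = d
        bright[i, : len(b)] = b
    return grid, dark, bright


def pointwise_condition_test(
    traces_by_participant: dict[int, dict[str, list[EpochedTrace]]],
    method: str = "participant_means_t",
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-value for the condition effect at every time point.

    ``participant_means_t`` (default): paired t-test across participants'
    condition-mean traces, vectorized over time.  ``mixed_model``: a
    trial-level linear mixed model with a participant random intercept at
    each time point (orders of magnitude slower; same asymptotics for
    balanced designs).  Time points with fewer than two complete
    participant pairs get p = NaN, treated downstream as non-significant.
    Returns ``(t_rel_ms, p_values)``.
    """
    if method == "participant_means_t":
        grid, dark, bright = participant_condition_means(traces_by_participant)
        diff = dark - bright
        n = np.sum(~np.isnan(diff), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(diff, axis=0)
            sd = np.nanstd(diff, axis=0, ddof=1)
            tval = mean / (sd / np.sqrt(n))
        p = np.full(grid.shape, np.nan)
        ok = (n >= 2) & (sd > 0)
        p[ok] = 2.0 * sps.t.sf(np.abs(tval[ok]), n[ok] - 1)
        # degenerate but well-defined case: no difference anywhere
        p[(n >= 2) & (sd == 0) & (mean == 0)] = 1.0
        return grid, p
    if method == "mixed_model":
        return _pointwise_mixed_model(traces_by_participant)
    raise ValueError(f"unknown pointwise test method {method!r}")


def _pointwise_mixed_model(traces_by_participant):
    import pandas as pd
    import statsmodels.formula.api as smf
    import warnings

    rows = []
    for pid, conds in traces_by_participant.items():
        for cond, traces in conds.items():
            for k, tr in enumerate(traces):
                rows.append((pid, cond, k, tr.t_rel, tr.pupil_norm))
    n = max(len(t) for *_, t, _ in rows)
    dt = rows[0][3][1] - rows[0][3][0]
    grid = rows[0][3][0] + dt * np.arange(n)
    p = np.full(n, np.nan)
    for i in range(n):
        recs = [
            (pid, cond, vals[i])
            for pid, cond, _, t, vals in rows
            if len(vals) > i and not np.isnan(vals[i])
        ]
        df = pd.DataFrame(recs, columns=["participant", "condition", "pupil"])
        if df.participant.nunique() < 2 or df.condition.nunique() < 2:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(
                    "pupil ~ C(condition)", df, groups=df["participant"]
                ).fit(reml=True, method="lbfgs")
            p[i] = float(fit.pvalues.iloc[1])
        except Exception:
            p[i] = np.nan  # non-convergence: treated as non-significant
    return grid, p


def divergence_onset(
    p_values: np.ndarray,
    t_rel: np.ndarray,
    alpha: float = 0.05,
    run_ms: float = 200.0,
    method: str = "participant_means_t",
) -> DivergenceResult:
    """First time point opening >= ``run_ms`` of consecutive significance.

    The run criterion (200 consecutive samples at 1000 Hz) is expressed as
    a duration and converted to samples at the series' own rate.  NaN
    p-values break a run.  Returns onset None when no qualifying run
    exists or the series is shorter than the run.
    """
    p_values = np.asarray(p_values, dtype=float)
    t_rel = np.asarray(t_rel, dtype=float)
    dt = t_rel[1] - t_rel[0] if len(t_rel) > 1 else np.nan
    run = max(int(round(run_ms / dt)), 1)
    sig = np.nan_to_num(p_values, nan=1.0) < alpha
    onset = None
    if len(sig) >= run:
        count = 0
        for i, s in enumerate(sig):
            count = count + 1 if s else 0
            if count >= run:
                onset = float(t_rel[i - run + 1])
                break
    return DivergenceResult(
        onset_ms=onset,
        p_values=p_values,
        t_rel=t_rel,
        run_samples=run,
        alpha=alpha,
        method=method,
    )
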