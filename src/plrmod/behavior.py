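"""Linking pupil-size modulation to behavioral cueing effects.

For the speeded (RT) design the per-participant link uses a rank-order
bin pairing: validly cued trials are sorted by RT from fast to slow and
split into four bins; invalidly cued trials are sorted from slow to fast
and split likewise; bin k of one list is paired with bin k of the other.
The first pair (fastest valid vs slowest invalid) carries a very large
cueing effect, the last a negligible or inverted one, so bin-level cueing
effects are non-increasing by construction.  Each pair's pupil-size
modulation is the signed area statistic computed over that pair's trials,
and a linear mixed model (random participant intercept) estimates the
modulation-vs-cueing-effect slope.

For the accuracy design the cueing effect is the percentage-point
accuracy difference (valid minus invalid) per participant, related to the
per-participant modulation by a between-subject Pearson correlation.
Effect sizes are Cohen's d of per-participant effects against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedTrace
from .stats import condition_traces, modulation_area

__all__ = [
    "BinPairing",
    "ModelFit",
    "EffectSizes",
    "rank_order_bins",
    "bin_modulation",
    "fit_modulation_model",
    "participant_correlation",
    "cohens_d_vs_zero",
]


@dataclass
class BinPairing:
    """One paired valid/invalid RT bin for one participant."""

    participant: int
    bin_index: int  # 1-based
    valid_trials: list[int]  # trial ids, RT-ascending quartile
    invalid_trials: list[int]  # trial ids, RT-descending quartile
    cueing_effect: float  # ms, mean invalid RT - mean valid RT
    modulation: float | None = None  # pupil_norm x s, filled by bin_modulation


@dataclass
class ModelFit:
    """Fixed-effect slope of modulation on cueing effect."""

    slope: float
    t_value: float
    p_value: float
    method: str  # "mixed_model" | "ols_cluster"
    n_bins: int
    n_participants: int


@dataclass
class EffectSizes:
    """Cohen's d (vs 0) for the behavioral and pupil effects."""

    d_behavior: float
    d_pupil: float
    behavior_effects: np.ndarray
    pupil_effects: np.ndarray


def _split_bins(items: list, n_bins: int) -> list[list]:
    """Contiguous split; the remainder goes to the earliest bins."""
    out = np.array_split(np.arange(len(items)), n_bins)
    return [[items[i] for i in idx] for idx in out]


def rank_order_bins(
    valid: list[tuple[int, float]],
    invalid: list[tuple[int, float]],
    participant: int = 0,
    n_bins: int = 4,
) -> list[BinPairing]:
    """Pair RT quartiles of valid and invalid trials.

    ``valid``/``invalid`` are ``(trial_id, rt_ms)`` pairs.  Valid trials
    are sorted by RT ascending, invalid descending (ties broken by trial
    id for reproducibility), each split into ``n_bins`` contiguous groups
    with any remainder placed in the earliest bins, and bin k is paired
    with bin k.  Raises when either side has fewer than ``n_bins`` trials.
    """
    if len(valid) < n_bins or len(invalid) < n_bins:
        raise ValueError(
            f"participant {participant}: need >= {n_bins} valid and invalid trials "
            f"(got {len(valid)}, {len(invalid)})"
        )
    v_sorted = sorted(valid, key=lambda x: (x[1], x[0]))
    i_sorted = sorted(invalid, key=lambda x: (-x[1], x[0]))
    v_bins = _split_bins(v_sorted, n_bins)
    i_bins = _split_bins(i_sorted, n_bins)
    out = []
    for k, (vb, ib) in enumerate(zip(v_bins, i_bins), start=1):
        effect = float(np.mean([rt for _, rt in ib]) - np.mean([rt for _, rt in vb]))
        out.append(
            BinPairing(
                participant=participant,
                bin_index=k,
                valid_trials=[tid for tid, _ in vb],
                invalid_trials=[tid for tid, _ in ib],
                cueing_effect=effect,
            )
        )
    return out


def bin_modulation(
    pairing: BinPairing,
    epoched: dict[int, tuple[str, EpochedTrace]],
    window: tuple[float, float] = (1000.0, 2000.0),
) -> float | None:
    """Modulation-area statistic over one bin pair's trials.

    ``epoched`` maps trial id to ``(attend_condition, cue_target trace)``.
    Condition traces are built from the union of the bin's valid and
    invalid trials; returns None (bin dropped from the model) when either
    condition is empty within the bin or the window is not covered.
    """
    ids = pairing.valid_trials + pairing.invalid_trials
    dark = [epoched[i][1] for i in ids if i in epoched and epoched[i][0] == "dark"]
    bright = [epoched[i][1] for i in ids if i in epoched and epoched[i][0] == "bright"]
    if not dark or not bright:
        return None
    try:
        result = modulation_area(condition_traces(dark, bright), window)
    except ValueError:
        return None
    pairing.modulation = result.area
    return result.area


def fit_modulation_model(bins: list[BinPairing]) -> ModelFit:
    """Mixed model of bin-level modulation on bin-level cueing effect.

    Random participant intercept, Wald inference on the fixed-effect
    slope.  A singular fit falls back to OLS with cluster-robust
    (by participant) standard errors, flagged in ``method``.
    """
    import pandas as pd
    import statsmodels.formula.api as smf

    rows = [
        (b.participant, b.cueing_effect, b.modulation)
        for b in bins
        if b.modulation is not None
    ]
    df = pd.DataFrame(rows, columns=["participant", "cueing_effect", "modulation"])
    n_participants = df.participant.nunique()
    if n_participants < 2 or len(df) < 4:
        raise ValueError("too few bins/participants to fit the modulation model")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "modulation ~ cueing_effect", df, groups=df["participant"]
            ).fit(reml=True)
        if not np.isfinite(fit.bse_fe.iloc[1]):
            raise np.linalg.LinAlgError("singular mixed model")
        return ModelFit(
            slope=float(fit.fe_params.iloc[1]),
            t_value=float(fit.tvalues.iloc[1]),
            p_value=float(fit.pvalues.iloc[1]),
            method="mixed_model",
            n_bins=len(df),
            n_participants=n_participants,
        )
    except (np.linalg.LinAlgError, ValueError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols("modulation ~ cueing_effect", df).fit(
                cov_type="cluster", cov_kwds={"groups": df["participant"]}
            )
        return ModelFit(
            slope=float(ols.params.iloc[1]),
            t_value=float(ols.tvalues.iloc[1]),
            p_value=float(ols.pvalues.iloc[1]),
            method="ols_cluster",
            n_bins=len(df),
            n_participants=n_participants,
        )


def participant_correlation(
    cueing_effects: np.ndarray, modulations: np.ndarray
) -> tuple[float, float]:
    """Between-subject Pearson correlation of cueing effect and modulation."""
    from scipy.stats import pearsonr

    x = np.asarray(cueing_effects, dtype=float)
    y = np.asarray(modulations, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired participant values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def cohens_d_vs_zero(effects: np.ndarray) -> float:
    """Cohen's d of per-participant effects against zero: mean / sample SD."""
    x = np.asarray(effects, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 effects")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Cohen's d undefined: zero variance")
    return float(x.mean() / sd)
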