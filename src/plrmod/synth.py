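"""Synthetic Posner-cueing pupillometry experiments with known ground truth.

The generator emulates the two study designs the analysis pipeline is built
for: a covert-attention cueing task on a display split into a bright and a
dark half, recorded with a 1000 Hz video eye tracker.  Each trial yields a
sample stream (pupil area + gaze) and a behavioral record.  The noise-free
pupil trace is

    baseline_area * (1 - PLR constriction + task-evoked dilation
                       - attention term)

where the PLR constriction (visual cue only, i.e. experiment 1) is a
gamma-shaped kernel whose velocity crosses the 0.5 /s criterion exactly at
the drawn latency (N(241, 25) ms by default), dilation is a linear ramp
from cue onset, and the attention term is a ramp starting at the
attentional divergence onset (~700 ms post-cue) that saturates over 500 ms
at +modulation/2 on attend-bright trials and -modulation/2 on attend-dark
trials, so the dark-minus-bright asymptote equals ``attn_modulation``.
Measurement noise is white; physiological drift ("hippus") is an
Ornstein-Uhlenbeck process.  Blinks are dropout intervals with 20 ms
partial-occlusion shoulders; gaze jitters around fixation with a slow
drift whose trial-mean provides the bias the pairing control removes.

A latent per-trial attention gain couples the pupil modulation to behavior
(faster valid / slower invalid responses when the gain is high), which is
what the rank-order bin analysis is designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter

from .preprocess import SampleSeries

__all__ = [
    "ObserverParams",
    "IntervalSpec",
    "StaircaseRule",
    "ExperimentConfig",
    "TrialCondition",
    "SimulatedExperiment",
    "ConfigurationError",
    "exp1_config",
    "exp2_config",
    "make_observers",
    "simulate_trial_trace",
    "simulate_staircase",
    "simulate_experiment",
    "plr_kernel_onset_shift",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class ObserverParams:
    """Generative parameters for one simulated observer.

    Pupil values are fractions of ``baseline_pupil`` (arbitrary area
    units); times are ms; rates are per second or per minute as noted.
    """

    baseline_pupil: float = 1000.0  # arbitrary area units
    plr_latency_mean: float = 241.0  # ms, cue-evoked constriction latency
    plr_latency_sd: float = 25.0
    plr_amplitude: float = 0.30  # fraction of baseline area
    plr_tau_ms: float = 150.0  # gamma-kernel time scale
    attn_divergence_onset: float = 700.0  # ms post-cue
    attn_modulation: float = 0.035  # dark-minus-bright asymptote, fraction
    attn_ramp_ms: float = 500.0  # attention ramp saturation time
    attn_gain_sd: float = 0.5  # log-SD of the per-trial attention gain
    dilation_rate: float = 0.03  # task-evoked dilation, fraction/s
    noise_sd: float = 0.01  # white measurement noise, fraction
    drift_sd: float = 0.015  # slow hippus-like drift (OU), fraction
    drift_tau_ms: float = 500.0  # OU time constant
    blink_rate: float = 10.0  # blinks/min
    blink_duration_mean: float = 120.0  # ms of full dropout
    gaze_jitter_sd: float = 0.4  # deg, fixational drift SD
    gaze_tau_ms: float = 300.0
    rt_valid_mean: float = 535.0  # ms
    rt_invalid_mean: float = 685.0
    rt_sd: float = 110.0
    rt_attention_coupling_ms: float = 100.0  # RT shift per unit attention gain
    error_rate_valid: float = 0.11  # speeded task (experiment 1)
    error_rate_invalid: float = 0.20
    lapse_rate: float = 0.02  # probability of a stimulus-independent error
    psychometric_threshold: float = 18.0  # % signal-to-noise
    psychometric_slope: float = 5.0  # % SNR per unit z
    invalid_threshold_shift: float = 3.5  # threshold penalty on invalid trials

    def __post_init__(self) -> None:
        if self.baseline_pupil <= 0:
            raise ConfigurationError("baseline_pupil must be positive")
        for name in (
            "plr_latency_sd", "noise_sd", "drift_sd", "blink_rate",
            "blink_duration_mean", "gaze_jitter_sd", "rt_sd", "attn_gain_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (0 <= self.plr_amplitude < 1 and 0 <= self.attn_modulation < 1):
            raise ConfigurationError("plr_amplitude and attn_modulation must be in [0, 1)")
        if not (0 <= self.lapse_rate <= 1):
            raise ConfigurationError("lapse_rate must be a probability")
        if self.rt_invalid_mean < self.rt_valid_mean:
            raise ConfigurationError("rt_invalid_mean must be >= rt_valid_mean")


@dataclass
class IntervalSpec:
    """Cue-target interval distribution: truncated normal or uniform (ms)."""

    kind: str  # "normal" | "uniform"
    mean: float = 2500.0
    sd: float = 500.0
    minimum: float = 1500.0
    maximum: float = 3000.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "normal":
            while True:
                x = rng.normal(self.mean, self.sd)
                if x >= self.minimum:
                    return float(x)
        if self.kind == "uniform":
            return float(rng.uniform(self.minimum, self.maximum))
        raise ConfigurationError(f"unknown interval distribution {self.kind!r}")


@dataclass
class StaircaseRule:
    """Adaptive staircase specification for the orientation task.

    ``weighted`` is an up/down rule whose up step is twice the down step
    (steps are multiplicative, ``step_percent`` per step), converging at
    2/3 correct; ``transformed`` is the 1-up-2-down rule (one error up,
    two consecutive correct down, equal steps), converging at 70.7%.
    """

    enabled: bool = True
    step_percent: float = 5.0
    start_snr: float = 40.0
    variant: str = "weighted"  # "weighted" | "transformed"
    min_snr: float = 1.0
    max_snr: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.start_snr <= self.max_snr):
            raise ConfigurationError("start_snr must be in (0, max_snr]")
        if self.variant not in ("weighted", "transformed"):
            raise ConfigurationError(f"unknown staircase variant {self.variant!r}")

    @property
    def convergence_accuracy(self) -> float:
        """Accuracy the rule converges to, from its equilibrium condition."""
        if self.variant == "weighted":
            # p * step_down = (1 - p) * step_up with step_up = 2 * step_down
            return 2.0 / 3.0
        return 0.5 ** 0.5  # transformed 1-up-2-down: p^2 = 1/2


@dataclass
class ExperimentConfig:
    """Design parameters of one simulated experiment."""

    experiment: str  # "exp1" | "exp2"
    n_participants: int = 15
    n_trials: int = 160
    cue_validity: float = 0.75
    cue_target_interval: IntervalSpec = field(
        default_factory=lambda: IntervalSpec(kind="normal")
    )
    sampling_rate: float = 1000.0  # Hz; 250 Hz is the fast-test option
    baseline_duration: float = 200.0  # ms of pre-cue trace
    target_duration: float = 100.0  # ms
    response_timeout: float = 5000.0  # ms
    staircase: StaircaseRule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ConfigurationError(f"unknown experiment {self.experiment!r}")
        if not (0.5 < self.cue_validity < 1):
            raise ConfigurationError("cue_validity must be in (0.5, 1)")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.n_trials % 4 != 0:
            raise ConfigurationError(
                "n_trials must be divisible by the 4 cue-side x bright-side cells"
            )
        if self.baseline_duration < 100.0:
            raise ConfigurationError("baseline_duration must cover the 100 ms baseline epoch")


def exp1_config(**overrides) -> ExperimentConfig:
    """Speeded RT task: visual arrow cue, 75% validity, 160 trials."""
    base = dict(
        experiment="exp1",
        n_trials=160,
        cue_validity=0.75,
        cue_target_interval=IntervalSpec(kind="normal", mean=2500.0, sd=500.0, minimum=1500.0),
        staircase=None,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def exp2_config(**overrides) -> ExperimentConfig:
    """Unspeeded accuracy task: auditory cue, 80% validity, 240 trials, staircase."""
    base = dict(
        experiment="exp2",
        n_trials=240,
        cue_validity=0.80,
        cue_target_interval=IntervalSpec(kind="uniform", minimum=1500.0, maximum=3000.0),
        staircase=StaircaseRule(),
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def make_observers(
    n: int,
    experiment: str,
    rng: np.random.Generator,
    attn_modulation_mean: float = 0.035,
    attn_modulation_sd: float = 0.02,
    cueing_effect_sd: float = 130.0,
    attention_coupling: float = 0.6,
    **overrides,
) -> list[ObserverParams]:
    """Draw a sample of observers with correlated attention traits.

    A latent attention strength couples each observer's pupil modulation to
    their behavioral cueing effect (RT effect in experiment 1, accuracy
    penalty on invalid trials in experiment 2), producing the
    between-observer association the analysis estimates.  Setting
    ``attn_modulation_sd=0`` (and passing explicit values via
    ``overrides``) yields homogeneous observers for calibration studies.
    """
    observers = []
    for _ in range(n):
        latent = rng.normal()
        resid = rng.normal()
        mix = attention_coupling * latent + np.sqrt(1 - attention_coupling**2) * resid
        mod = max(attn_modulation_mean + attn_modulation_sd * latent, 0.0)
        params = dict(
            attn_modulation=mod,
            # divergence arises later after a visual cue than an auditory one
            attn_divergence_onset=716.0 if experiment == "exp1" else 656.0,
        )
        if experiment == "exp1":
            effect = max(150.0 + cueing_effect_sd * mix, 0.0)
            valid = rng.normal(535.0, 30.0)
            params.update(rt_valid_mean=valid, rt_invalid_mean=valid + effect)
        else:
            params.update(
                rt_valid_mean=1000.0,
                rt_invalid_mean=1000.0,
                rt_sd=500.0,
                invalid_threshold_shift=max(3.5 + 1.5 * mix, 0.0),
            )
        params.update(overrides)
        observers.append(ObserverParams(**params))
    return observers


# ---------------------------------------------------------------------------
# trial-level generative model


@dataclass
class TrialCondition:
    """Condition of a single trial handed to the trace generator."""

    attend_side: str  # "left" | "right" (cued side)
    bright_side: str  # "left" | "right"
    soa_ms: float  # cue-target interval
    rt_ms: float  # response time after target onset
    experiment: str = "exp1"
    sampling_rate: float = 1000.0
    baseline_duration: float = 200.0
    attn_gain: float = 1.0

    @property
    def attend_condition(self) -> str:
        return "bright" if self.attend_side == self.bright_side else "dark"


def _gamma2_cdf(u: np.ndarray, tau: float) -> np.ndarray:
    """Shape-2 gamma CDF: smooth 0->1 rise with zero initial slope."""
    u = np.maximum(u, 0.0)
    return 1.0 - (1.0 + u / tau) * np.exp(-u / tau)


def plr_kernel_onset_shift(
    params: ObserverParams, velocity_threshold: float = 0.5
) -> float:
    """Time (ms) from kernel onset to the velocity-criterion crossing.

    The drawn latency is defined as the moment the noise-free trace's
    constriction velocity reaches ``velocity_threshold`` (normalized
    size/s), so the kernel is shifted earlier by this amount.  The trace
    velocity is the constriction-kernel velocity minus the concurrent
    dilation ramp.
    """
    tau = params.plr_tau_ms / 1000.0
    amp = params.plr_amplitude

    def vel(u):  # constriction speed (positive) net of dilation, at u seconds
        return amp * u * np.exp(-u / tau) / tau**2 - params.dilation_rate

    peak = vel(tau)
    if peak <= velocity_threshold:
        return 0.0  # kernel never reaches the criterion; latency = onset
    return 1000.0 * brentq(lambda u: vel(u) - velocity_threshold, 1e-9, tau)


def _ou_noise(n: int, sd: float, tau_ms: float, dt_ms: float, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-dt_ms / tau_ms)
    eps = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_trial_trace(
    params: ObserverParams,
    condition: TrialCondition,
    seed: int | np.random.Generator,
    plr_latency_ms: float | None = None,
) -> tuple[SampleSeries, dict]:
    """Generate one trial's sample stream.

    Returns the series and a ground-truth dict (drawn PLR latency, blink
    intervals, attention sign).  The trace covers ``baseline_duration`` ms
    before cue onset (t = 0) through ~100 ms past the response.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1000.0 / condition.sampling_rate
    if condition.soa_ms < condition.baseline_duration:
        raise ConfigurationError("cue-target interval shorter than the baseline segment")
    t_end = condition.soa_ms + condition.rt_ms + 100.0
    t = np.arange(-condition.baseline_duration, t_end, dt)
    ts = t / 1000.0  # seconds

    signal = np.ones_like(t)
    truth: dict = {"attend_condition": condition.attend_condition}

    # cue-evoked constriction: visual cue only (experiment 1)
    if condition.experiment == "exp1":
        if plr_latency_ms is None:
            plr_latency_ms = rng.normal(params.plr_latency_mean, params.plr_latency_sd)
        onset = plr_latency_ms - plr_kernel_onset_shift(params)
        signal -= params.plr_amplitude * _gamma2_cdf(
            (t - onset) / 1000.0, params.plr_tau_ms / 1000.0
        )
        truth["plr_latency_ms"] = float(plr_latency_ms)

    # task-evoked dilation from cue onset
    signal += params.dilation_rate * np.maximum(ts, 0.0)

    # attention term: ramp saturating at +/- modulation/2
    ramp = np.clip((t - params.attn_divergence_onset) / params.attn_ramp_ms, 0.0, 1.0)
    half = 0.5 * params.attn_modulation * condition.attn_gain
    sign = 1.0 if condition.attend_condition == "bright" else -1.0
    signal -= sign * half * ramp
    truth["attn_half_amplitude"] = float(sign * half)

    # noise: white measurement noise + slow hippus-like drift
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=len(t))
    signal = signal + _ou_noise(len(t), params.drift_sd, params.drift_tau_ms, dt, rng)
    pupil = params.baseline_pupil * signal

    # blinks: dropout with 20 ms linear occlusion shoulders
    blink_intervals = []
    if params.blink_rate > 0:
        duration_min = (t[-1] - t[0]) / 60000.0
        for _ in range(rng.poisson(params.blink_rate * duration_min)):
            dur = max(rng.normal(params.blink_duration_mean, 0.2 * params.blink_duration_mean), 20.0)
            start = rng.uniform(t[0] + 150.0, t[-1] - dur - 150.0)
            blink_intervals.append((float(start), float(start + dur)))
        for s, e in blink_intervals:
            shoulder = 20.0
            pre = (t >= s - shoulder) & (t < s)
            post = (t >= e) & (t < e + shoulder)
            pupil[pre] *= (s - t[pre]) / shoulder
            pupil[post] *= (t[post] - e) / shoulder
            pupil[(t >= s) & (t < e)] = np.nan
    truth["blinks"] = blink_intervals

    # gaze: fixational drift (OU) + tracker noise, per axis
    gaze_x = _ou_noise(len(t), params.gaze_jitter_sd, params.gaze_tau_ms, dt, rng)
    gaze_y = _ou_noise(len(t), params.gaze_jitter_sd, params.gaze_tau_ms, dt, rng)
    gaze_x = gaze_x + rng.normal(0.0, 0.02, size=len(t))
    gaze_y = gaze_y + rng.normal(0.0, 0.02, size=len(t))

    series = SampleSeries(t=t, pupil=pupil, gaze_x=gaze_x, gaze_y=gaze_y)
    return series, truth


# ---------------------------------------------------------------------------
# staircase


def simulate_staircase(
    observer: ObserverParams,
    rule: StaircaseRule,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    respond: Callable[[float], bool] | None = None,
) -> list[tuple[float, bool]]:
    """Run an adaptive staircase, returning the (snr, correct) trajectory.

    Responses come from the observer's psychometric function
    ``p(correct) = (1 - lapse) * (0.5 + 0.5 * Phi((snr - threshold)/slope))``
    unless an explicit ``respond(snr) -> bool`` rule is supplied.
    """
    from scipy.stats import norm

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snr = rule.start_snr
    down = 1.0 + rule.step_percent / 100.0
    trajectory: list[tuple[float, bool]] = []
    consecutive_correct = 0
    for _ in range(n_trials):
        if respond is not None:
            correct = bool(respond(snr))
        else:
            p = (1.0 - observer.lapse_rate) * (
                0.5 + 0.5 * norm.cdf((snr - observer.psychometric_threshold) / observer.psychometric_slope)
            )
            correct = bool(rng.random() < p)
        trajectory.append((float(snr), correct))
        if rule.variant == "weighted":
            snr = snr / down if correct else snr * down**2
        else:  # transformed 1-up-2-down
            if correct:
                consecutive_correct += 1
                if consecutive_correct >= 2:
                    snr /= down
                    consecutive_correct = 0
            else:
                snr *= down
                consecutive_correct = 0
        snr = float(np.clip(snr, rule.min_snr, rule.max_snr))
    return trajectory


# ---------------------------------------------------------------------------
# whole experiments


@dataclass
class SimulatedExperiment:
    """One simulated experiment: trial table, sample streams, ground truth."""

    config: ExperimentConfig
    observers: list[ObserverParams]
    trials: pd.DataFrame
    samples: dict[tuple[int, int], SampleSeries]
    ground_truth: dict

    def samples_frame(self) -> pd.DataFrame:
        """Tidy long-format sample table (one row per sample)."""
        parts = []
        for (p, tr), series in self.samples.items():
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
        return pd.concat(parts, ignore_index=True)


def _balanced_factors(n_trials: int, rng: np.random.Generator) -> pd.DataFrame:
    """Cue side x bright side balanced to +/-0 within participant, shuffled."""
    cells = [(c, b) for c in ("left", "right") for b in ("left", "right")]
    reps = n_trials // len(cells)
    rows = [cell for cell in cells for _ in range(reps)]
    order = rng.permutation(len(rows))
    return pd.DataFrame(
        [rows[i] for i in order], columns=["cue_side", "bright_side"]
    )


def _shifted_lognormal(mean: float, sd: float, shift: float, rng) -> float:
    """Draw rt = shift + LogNormal matched to the residual mean and sd."""
    m = max(mean - shift, 1.0)
    sigma2 = np.log(1.0 + (sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return float(shift + rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_experiment(
    config: ExperimentConfig,
    observers: list[ObserverParams] | None = None,
) -> SimulatedExperiment:
    """Simulate a complete experiment.

    Returns per-trial sample streams, the trial table (design factors and
    behavioral outcomes) and a ground-truth record of every generating
    parameter.  Identical ``(config, observers)`` give bit-identical
    output.
    """
    root = np.random.SeedSequence(config.seed)
    obs_seq, *part_seqs = root.spawn(config.n_participants + 1)
    if observers is None:
        observers = make_observers(
            config.n_participants, config.experiment, np.random.default_rng(obs_seq)
        )
    if len(observers) != config.n_participants:
        raise ConfigurationError("observers length must equal n_participants")

    rows = []
    samples: dict[tuple[int, int], SampleSeries] = {}
    truth: dict = {
        "config": _config_record(config),
        "observers": [asdict(o) for o in observers],
        "trials": {},
    }

    for p, (params, seq) in enumerate(zip(observers, part_seqs)):
        rng = np.random.default_rng(seq)
        factors = _balanced_factors(config.n_trials, rng)
        # independent staircases per target background (experiment 2)
        stair_state: dict[str, float] = {}
        stair_cc = {"bright": 0, "dark": 0}  # consecutive-correct counters
        if config.staircase is not None and config.staircase.enabled:
            stair_state = {
                "bright": config.staircase.start_snr,
                "dark": config.staircase.start_snr,
            }
        for tr in range(config.n_trials):
            cue_side = factors.cue_side.iloc[tr]
            bright_side = factors.bright_side.iloc[tr]
            valid = bool(rng.random() < config.cue_validity)
            target_side = cue_side if valid else ("left" if cue_side == "right" else "right")
            target_bg = "bright" if target_side == bright_side else "dark"
            soa = config.cue_target_interval.draw(rng)
            # unit-mean lognormal attention gain
            gain = float(rng.lognormal(-0.5 * params.attn_gain_sd**2, params.attn_gain_sd))

            # behavior
            shift = (gain - 1.0) * params.rt_attention_coupling_ms
            if valid:
                rt_mean = params.rt_valid_mean - shift
            else:
                rt_mean = params.rt_invalid_mean + shift
            rt = _shifted_lognormal(max(rt_mean, 250.0), params.rt_sd, 200.0, rng)
            timeout = rt > config.response_timeout
            snr_percent = np.nan
            if stair_state:
                from scipy.stats import norm

                snr_percent = stair_state[target_bg]
                thr = params.psychometric_threshold
                if not valid:
                    thr = thr + params.invalid_threshold_shift / max(gain, 0.25)
                p_correct = (1.0 - params.lapse_rate) * (
                    0.5 + 0.5 * norm.cdf((snr_percent - thr) / params.psychometric_slope)
                )
                correct = bool(rng.random() < p_correct)
                if valid:  # staircase tracks validly cued trials only
                    step = 1.0 + config.staircase.step_percent / 100.0
                    new = snr_percent
                    if config.staircase.variant == "weighted":
                        new = snr_percent / step if correct else snr_percent * step**2
                    else:  # transformed 1-up-2-down
                        if correct:
                            stair_cc[target_bg] += 1
                            if stair_cc[target_bg] >= 2:
                                new = snr_percent / step
                                stair_cc[target_bg] = 0
                        else:
                            new = snr_percent * step
                            stair_cc[target_bg] = 0
                    stair_state[target_bg] = float(
                        np.clip(new, config.staircase.min_snr, config.staircase.max_snr)
                    )
            else:
                err = params.error_rate_valid if valid else params.error_rate_invalid
                correct = bool(rng.random() >= err)

            cond = TrialCondition(
                attend_side=cue_side,
                bright_side=bright_side,
                soa_ms=soa,
                rt_ms=min(rt, config.response_timeout),
                experiment=config.experiment,
                sampling_rate=config.sampling_rate,
                baseline_duration=config.baseline_duration,
                attn_gain=gain,
            )
            series, trial_truth = simulate_trial_trace(params, cond, rng)
            samples[(p, tr)] = series
            trial_truth.update(soa_ms=soa, attn_gain=gain)
            truth["trials"][f"{p}:{tr}"] = trial_truth
            rows.append(
                dict(
                    participant=p,
                    trial=tr,
                    experiment=config.experiment,
                    cue_side=cue_side,
                    target_side=target_side,
                    validity="valid" if valid else "invalid",
                    bright_side=bright_side,
                    attend_condition=cond.attend_condition,
                    soa_ms=soa,
                    rt_ms=rt,
                    correct=correct,
                    timeout=timeout,
                    snr_percent=snr_percent,
                )
            )

    trials = pd.DataFrame(rows)
    return SimulatedExperiment(
        config=config, observers=observers, trials=trials, samples=samples, ground_truth=truth
    )


def _config_record(config: ExperimentConfig) -> dict:
    rec = asdict(config)
    return json.loads(json.dumps(rec, default=str))
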