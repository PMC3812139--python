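import numpy as np
import pytest

from plrmod.preprocess import SampleSeries
from plrmod.synth import ObserverParams, TrialCondition


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def quiet_observer():
    """Observer with no noise, drift or blinks: deterministic traces."""
    return ObserverParams(noise_sd=0.0, drift_sd=0.0, blink_rate=0.0, gaze_jitter_sd=0.0)


@pytest.fixture
def flat_series():
    """Constant 1000-unit pupil at 250 Hz, 4 s, gaze at fixation."""
    t = np.arange(-200.0, 3800.0, 4.0)
    return SampleSeries(
        t=t,
        pupil=np.full_like(t, 1000.0),
        gaze_x=np.zeros_like(t),
        gaze_y=np.zeros_like(t),
    )


def make_condition(
    attend_side="left",
    bright_side="right",
    soa_ms=2500.0,
    rt_ms=600.0,
    experiment="exp1",
    sampling_rate=250.0,
    **kw,
):
    return TrialCondition(
        attend_side=attend_side,
        bright_side=bright_side,
        soa_ms=soa_ms,
        rt_ms=rt_ms,
        experiment=experiment,
        sampling_rate=sampling_rate,
        **kw,
    )
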