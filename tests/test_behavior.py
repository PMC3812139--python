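"""Rank-order bin pairing and the modulation-behavior link statistics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_condition
from plrmod.behavior import (
    BinPairing,
    bin_modulation,
    cohens_d_vs_zero,
    fit_modulation_model,
    participant_correlation,
    rank_order_bins,
)
from plrmod.preprocess import EpochedTrace, segment_and_normalize
from plrmod.stats import condition_traces
from plrmod.synth import ObserverParams, simulate_trial_trace


def const_trace(value, n=600, dt=4.0):
    return EpochedTrace("cue_target", dt * np.arange(n), np.full(n, value))


class TestRankOrderBins:
    def test_hand_example_cueing_effects(self):
        valid = [(i, rt) for i, rt in enumerate(range(400, 541, 20))]  # 400..540
        invalid = [(100 + i, rt) for i, rt in enumerate(range(600, 661, 20))]
        bins = rank_order_bins(valid, invalid, participant=1)
        assert [b.cueing_effect for b in bins] == [250.0, 190.0, 130.0, 70.0]
        assert [len(b.valid_trials) for b in bins] == [2, 2, 2, 2]
        # fastest valid bin paired with slowest invalid bin
        assert bins[0].valid_trials == [0, 1]
        assert bins[0].invalid_trials == [103]

    def test_equal_rts_give_equal_effects(self):
        valid = [(i, 500.0) for i in range(8)]
        invalid = [(10 + i, 650.0) for i in range(8)]
        bins = rank_order_bins(valid, invalid)
        assert all(b.cueing_effect == 150.0 for b in bins)

    def test_remainder_goes_to_earliest_bins(self):
        valid = [(i, 400.0 + i) for i in range(9)]
        invalid = [(20 + i, 700.0 + i) for i in range(4)]
        bins = rank_order_bins(valid, invalid)
        assert [len(b.valid_trials) for b in bins] == [3, 2, 2, 2]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="participant 3"):
            rank_order_bins([(0, 400.0)], [(1, 600.0)] * 4, participant=3)

    def test_effects_non_increasing_for_any_rts(self, rng):
        for _ in range(30):
            nv, ni = rng.integers(4, 40, size=2)
            valid = [(i, r) for i, r in enumerate(rng.uniform(300, 900, nv))]
            invalid = [(100 + i, r) for i, r in enumerate(rng.uniform(300, 900, ni))]
            effects = [b.cueing_effect for b in rank_order_bins(valid, invalid)]
            assert all(a >= b for a, b in zip(effects, effects[1:]))


class TestBinModulation:
    def make_bin(self):
        return BinPairing(0, 1, valid_trials=[0, 1], invalid_trials=[2], cueing_effect=100.0)

    def test_constant_traces_give_constant_area(self):
        epoched = {
            0: ("dark", const_trace(1.02)),
            1: ("dark", const_trace(1.02)),
            2: ("bright", const_trace(1.00)),
        }
        assert bin_modulation(self.make_bin(), epoched) == pytest.approx(0.02, rel=1e-6)

    def test_label_swap_negates(self):
        epoched = {
            0: ("bright", const_trace(1.02)),
            1: ("bright", const_trace(1.02)),
            2: ("dark", const_trace(1.00)),
        }
        assert bin_modulation(self.make_bin(), epoched) == pytest.approx(-0.02, rel=1e-6)

    def test_empty_condition_drops_bin(self):
        epoched = {0: ("dark", const_trace(1.0)), 1: ("dark", const_trace(1.0)),
                   2: ("dark", const_trace(1.0))}
        assert bin_modulation(self.make_bin(), epoched) is None

    def test_bins_track_injected_attention_gain(self):
        # trials with a stronger injected gain must show stronger modulation;
        # rank correlation between bin mean gain and bin modulation
        rng = np.random.default_rng(7)
        obs = ObserverParams(attn_modulation=0.05, noise_sd=0.004, drift_sd=0.004,
                             blink_rate=0.0, attn_gain_sd=0.6)
        rhos = []
        for _ in range(10):
            trials, epoched = [], {}
            for i in range(48):
                gain = float(rng.lognormal(-0.18, 0.6))
                bright_side = "right" if i % 2 else "left"
                cond = make_condition("left", bright_side, soa_ms=2200.0, rt_ms=300.0,
                                      attn_gain=gain)
                s, _ = simulate_trial_trace(obs, cond, seed=rng)
                ep = segment_and_normalize(s, 0.0, 2200.0, 300.0)
                epoched[i] = (cond.attend_condition, ep["cue_target"])
                # RT coupled to the gain: strong attention -> fast valid RT
                trials.append((i, 600.0 - 200.0 * gain + rng.normal(0, 10), gain))
            valid = [(i, rt) for i, rt, _ in trials[:32]]
            invalid = [(i, 1300.0 - rt) for i, rt, _ in trials[32:]]
            bins = rank_order_bins(valid, invalid)
            gains = {i: g for i, _, g in trials}
            mean_gain, mods = [], []
            for b in bins:
                mod = bin_modulation(b, epoched)
                if mod is None:
                    continue
                mean_gain.append(np.mean([gains[i] for i in b.valid_trials + b.invalid_trials]))
                mods.append(mod)
            if len(mods) >= 3:
                rhos.append(spearmanr(mean_gain, mods).statistic)
        assert np.mean(rhos) > 0.8


class TestFitModulationModel:
    def test_exact_linear_relationship_recovered(self):
        bins = []
        for p in range(6):
            for k, eff in enumerate([250.0, 190.0, 130.0, 70.0]):
                bins.append(BinPairing(p, k + 1, [], [], eff,
                                       modulation=0.0001 * eff + 0.01))
        fit = fit_modulation_model(bins)
        assert fit.slope == pytest.approx(0.0001, abs=1e-6)
        assert fit.p_value < 1e-6

    def test_permuted_modulations_rarely_significant(self, rng):
        effects = np.tile([250.0, 190.0, 130.0, 70.0], 8)
        mods = 0.0001 * effects + rng.normal(0, 0.005, len(effects))
        big_t = 0
        for _ in range(50):
            perm = rng.permutation(mods)
            bins = [BinPairing(i // 4, i % 4 + 1, [], [], e, modulation=m)
                    for i, (e, m) in enumerate(zip(effects, perm))]
            if abs(fit_modulation_model(bins).t_value) >= 2:
                big_t += 1
        assert big_t <= 5

    def test_slope_recovery_within_two_se(self, rng):
        # simulate bin tables with a known slope; the fitted slope should fall
        # within 2 SE of truth in >= 90% of replicates
        beta = 2e-4
        hits, n_rep = 0, 30
        for _ in range(n_rep):
            bins = []
            for p in range(10):
                intercept = rng.normal(0.0, 0.01)
                for k, eff in enumerate(rng.uniform(0, 300, 4)):
                    mod = intercept + beta * eff + rng.normal(0, 0.005)
                    bins.append(BinPairing(p, k + 1, [], [], eff, modulation=mod))
            fit = fit_modulation_model(bins)
            se = abs(fit.slope / fit.t_value)
            if abs(fit.slope - beta) <= 2 * se:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestParticipantCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        r, _ = participant_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_constant_vector_is_signaled(self):
        with pytest.raises(ValueError, match="constant"):
            participant_correlation(np.ones(5), np.arange(5.0))

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, _ = participant_correlation(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)


class TestCohensD:
    def test_two_point_example(self):
        assert cohens_d_vs_zero([1.0, 3.0]) == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError, match="zero variance"):
            cohens_d_vs_zero([0.0, 0.0, 0.0])

    def test_matches_brute_force(self, rng):
        x = rng.normal(1, 2, 15)
        assert cohens_d_vs_zero(x) == pytest.approx(x.mean() / x.std(ddof=1), abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.normal(1, 2, 12)
        assert cohens_d_vs_zero(7.3 * x) == pytest.approx(cohens_d_vs_zero(x), abs=1e-12)


# property-based checks (derandomized)
from hypothesis import given, settings, strategies as st


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    valid=st.lists(st.floats(100, 3000), min_size=4, max_size=40),
    invalid=st.lists(st.floats(100, 3000), min_size=4, max_size=40),
)
def test_bin_effects_non_increasing_property(valid, invalid):
    """The sort-and-pair rule makes bin cueing effects non-increasing for
    any RT data whatsoever."""
    v = list(enumerate(valid))
    i = [(100 + k, rt) for k, rt in enumerate(invalid)]
    effects = [b.cueing_effect for b in rank_order_bins(v, i)]
    assert all(a >= b - 1e-9 for a, b in zip(effects, effects[1:]))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(x=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
       c=st.floats(1e-3, 1e3))
def test_cohens_d_scale_invariance_property(x, c):
    arr = np.asarray(x)
    if arr.std(ddof=1) < 1e-9:
        return
    assert cohens_d_vs_zero(c * arr) == pytest.approx(cohens_d_vs_zero(arr), rel=1e-9)
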