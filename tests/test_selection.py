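"""Discard rules, outlier bounds and the gaze-bias pairing control."""

import numpy as np
import pytest

from plrmod.selection import (
    TrialRecord,
    apply_selection,
    filter_gaze,
    filter_pupil_outliers,
    filter_rt_outliers,
    filter_timeouts,
    pair_gaze_bias,
)


def record(trial, rt=500.0, mean_pupil=1000.0, gaze_bias=0.0, max_dev=0.5,
           max_horiz=0.3, timeout=False, participant=0, validity="valid",
           attend="dark"):
    return TrialRecord(
        participant=participant, trial=trial, validity=validity,
        attend_condition=attend, rt=rt, correct=True, mean_pupil=mean_pupil,
        gaze_bias=gaze_bias, max_gaze_dev=max_dev, max_horiz_dev=max_horiz,
        timeout=timeout,
    )


class TestGazeFilter:
    def test_fixated_trials_kept(self):
        kept, discarded = filter_gaze([record(0), record(1)], "any_sample_radius", 2.0)
        assert len(kept) == 2 and not discarded

    def test_single_excursion_discards_trial(self):
        kept, discarded = filter_gaze([record(0, max_dev=2.1)], "any_sample_radius", 2.0)
        assert not kept and len(discarded) == 1

    def test_horizontal_band_mode(self):
        trials = [record(0, max_horiz=2.9), record(1, max_horiz=2.7)]
        kept, discarded = filter_gaze(trials, "horizontal_band", 2.8)
        assert [t.trial for t in kept] == [1]

    def test_discard_fraction_matches_per_sample_oracle(self, rng):
        # recompute the rule from raw samples and compare trial by trial
        trials, over = [], set()
        for i in range(200):
            gx = rng.normal(0, 0.7, 500)
            gy = rng.normal(0, 0.7, 500)
            dev = float(np.max(np.hypot(gx, gy)))
            if np.any(np.hypot(gx, gy) > 2.0):
                over.add(i)
            trials.append(record(i, max_dev=dev))
        kept, discarded = filter_gaze(trials, "any_sample_radius", 2.0)
        assert {t.trial for t in discarded} == over


class TestOutlierFilters:
    def test_single_pass_bound_hand_example(self):
        # ten 500 ms trials + one 1000 ms: mean 545.45, SD 150.76, bound 922.4
        trials = [record(i, rt=500.0) for i in range(10)] + [record(10, rt=1000.0)]
        kept, discarded = filter_rt_outliers(trials)
        assert [t.trial for t in discarded] == [10]
        assert len(kept) == 10

    def test_identical_values_keep_everything(self):
        trials = [record(i, rt=500.0) for i in range(8)]
        kept, discarded = filter_rt_outliers(trials)
        assert len(kept) == 8 and not discarded

    @pytest.mark.parametrize("attr,filt", [
        ("rt", filter_rt_outliers), ("mean_pupil", filter_pupil_outliers)
    ])
    def test_oracle_equality_on_random_data(self, rng, attr, filt):
        for _ in range(10):
            vals = rng.lognormal(6.3, 0.4, size=40)
            trials = [record(i, **{attr: v}) for i, v in enumerate(vals)]
            kept, discarded = filt(trials)
            mean, sd = vals.mean(), vals.std(ddof=1)
            oracle = {i for i, v in enumerate(vals) if abs(v - mean) > 2.5 * sd}
            assert {t.trial for t in discarded} == oracle

    def test_empty_input(self):
        kept, discarded = filter_pupil_outliers([])
        assert kept == [] and discarded == []

    @pytest.mark.parametrize("filt", [filter_rt_outliers, filter_pupil_outliers])
    def test_idempotent(self, rng, filt):
        trials = [record(i, rt=v, mean_pupil=v) for i, v in
                  enumerate(rng.normal(500, 80, 30))]
        kept, _ = filt(trials)
        again, dropped = filt(kept)
        # single-pass bound recomputed on the survivors may drop more only if
        # the bound tightens; idempotence is on an already-stable output
        stable, _ = filt(again)
        assert [t.trial for t in stable] == [t.trial for t in again] or not dropped


class TestTimeouts:
    def test_boundary(self):
        kept, _ = filter_timeouts([record(0, rt=4999.0)])
        assert len(kept) == 1
        _, discarded = filter_timeouts([record(1, rt=5001.0)])
        assert len(discarded) == 1
        _, discarded = filter_timeouts([record(2, rt=800.0, timeout=True)])
        assert len(discarded) == 1

    def test_mixed_set_equals_brute_force(self, rng):
        rts = rng.uniform(100, 6000, 50)
        trials = [record(i, rt=r) for i, r in enumerate(rts)]
        kept, discarded = filter_timeouts(trials)
        assert len(discarded) == int(np.sum(rts > 5000.0))


class TestPairGazeBias:
    def test_opposite_small_difference_paired(self):
        trials = [record(0, gaze_bias=0.10), record(1, gaze_bias=-0.06)]
        kept, discarded = pair_gaze_bias(trials)
        assert len(kept) == 2 and not discarded

    def test_same_sign_all_discarded(self):
        trials = [record(0, gaze_bias=0.50), record(1, gaze_bias=0.20)]
        kept, discarded = pair_gaze_bias(trials)
        assert not kept and len(discarded) == 2

    def test_pairs_respect_tolerance_pairwise(self, rng):
        trials = [record(i, gaze_bias=b) for i, b in
                  enumerate(rng.normal(0, 0.2, 60))]
        kept, _ = pair_gaze_bias(trials, tolerance=0.14)
        pos = sorted((t for t in kept if t.gaze_bias >= 0), key=lambda t: abs(t.gaze_bias))
        neg = sorted((t for t in kept if t.gaze_bias < 0), key=lambda t: abs(t.gaze_bias))
        assert len(pos) == len(neg)
        for a, b in zip(pos, neg):
            assert abs(a.gaze_bias + b.gaze_bias) < 0.14

    def test_greedy_cardinality_equals_optimal_matching(self, rng):
        import networkx as nx

        for _ in range(120):
            n = rng.integers(2, 13)
            biases = rng.normal(0, 0.15, n)
            trials = [record(i, gaze_bias=b) for i, b in enumerate(biases)]
            kept, _ = pair_gaze_bias(trials, tolerance=0.14, group_by_condition=False)
            g = nx.Graph()
            pos = [t for t in trials if t.gaze_bias >= 0]
            neg = [t for t in trials if t.gaze_bias < 0]
            g.add_nodes_from(("p", t.trial) for t in pos)
            g.add_nodes_from(("n", t.trial) for t in neg)
            for a in pos:
                for b in neg:
                    if abs(a.gaze_bias + b.gaze_bias) < 0.14:
                        g.add_edge(("p", a.trial), ("n", b.trial))
            optimal = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
            assert len(kept) == 2 * len(optimal)

    def test_retained_mean_bias_small_under_symmetric_jitter(self, rng):
        trials = [record(i, gaze_bias=b) for i, b in enumerate(rng.normal(0, 0.2, 400))]
        kept, _ = pair_gaze_bias(trials, tolerance=0.14, group_by_condition=False)
        assert abs(np.mean([t.gaze_bias for t in kept])) < 0.07

    def test_pairing_idempotent(self, rng):
        trials = [record(i, gaze_bias=b) for i, b in enumerate(rng.normal(0, 0.2, 50))]
        kept, _ = pair_gaze_bias(trials)
        again, dropped = pair_gaze_bias(kept)
        assert not dropped and [t.trial for t in again] == [t.trial for t in kept]


class TestApplySelection:
    def test_reason_codes_partition_total(self, rng):
        trials = [
            record(i, rt=rng.uniform(300, 900), gaze_bias=rng.normal(0, 0.2),
                   max_dev=rng.uniform(0, 3))
            for i in range(100)
        ]
        kept, report = apply_selection(trials, experiment="exp1")
        assert report.surviving == len(kept)
        assert report.surviving + sum(report.discarded.values()) == report.total

    def test_exp2_profile_skips_rt_and_pairing(self):
        trials = [record(i, rt=400.0) for i in range(12)]
        _, report = apply_selection(trials, experiment="exp2")
        assert set(report.discarded) == {"gaze", "timeout", "pupil_outlier"}


# property-based check (derandomized)
from hypothesis import given, settings, strategies as st


@settings(max_examples=80, derandomize=True, deadline=None)
@given(biases=st.lists(st.floats(-0.5, 0.5), min_size=0, max_size=20))
def test_pairing_never_violates_tolerance_property(biases):
    """Whatever the biases, retained trials form opposite-sign pairs whose
    sum stays below the tolerance, and the filter is idempotent."""
    trials = [record(i, gaze_bias=b) for i, b in enumerate(biases)]
    kept, _ = pair_gaze_bias(trials, tolerance=0.14, group_by_condition=False)
    pos = sorted((t for t in kept if t.gaze_bias >= 0), key=lambda t: abs(t.gaze_bias))
    neg = sorted((t for t in kept if t.gaze_bias < 0), key=lambda t: abs(t.gaze_bias))
    assert len(pos) == len(neg)
    for a, b in zip(pos, neg):
        assert abs(a.gaze_bias + b.gaze_bias) < 0.14
    again, dropped = pair_gaze_bias(kept, tolerance=0.14, group_by_condition=False)
    assert not dropped
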