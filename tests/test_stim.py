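"""Stimulation-effect analyses: binarization, window labels, behavioral
contrasts, burst-aligned beta, conditional splits."""

import numpy as np
import pytest

from stnadapt.schedule import StimSchedule, StimScheduleConfig, generate_dbs_schedule
from stnadapt.stats import SlidingWindowDesign
from stnadapt.stim import (
    StimWindowLabels,
    binarize_stimulation,
    cluster_permutation_labels,
    conditional_effects,
    group_t_series,
    stim_aligned_beta,
    stim_behavior_contrast,
    window_stim_labels,
    windowed_beta_contrast,
)

RATE = 1000.0


@pytest.fixture(scope="module")
def schedule():
    return generate_dbs_schedule(StimScheduleConfig(seed=21), duration=400.0)


class TestBinarize:
    def test_all_zero_intensity_is_off(self):
        assert not binarize_stimulation(np.zeros(1000), 2.0).any()

    def test_ramps_off_plateau_on(self, schedule):
        n = int(schedule.duration * RATE)
        inten = schedule.intensity(RATE, n)
        on = binarize_stimulation(inten, schedule.amplitude)
        assert np.array_equal(on, schedule.suprathreshold(RATE, n))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            binarize_stimulation(np.array([-0.1, 1.0]), 2.0)


class TestWindowLabels:
    def test_burst_inside_window_is_on(self):
        on = np.zeros(5000, dtype=bool)
        on[1040:1060] = True  # 1.04-1.06 s
        d = SlidingWindowDesign(0.0, 0.3, 0.1, 0.01)
        lab = window_stim_labels(on, RATE, np.array([1.0]), d)
        w = lab.labels[0]
        starts = d.starts
        assert w[np.isclose(starts, 0.0)][0]  # [1.0, 1.1) overlaps
        assert w[np.isclose(starts, 0.05)][0]
        assert not w[np.isclose(starts, 0.07)][0]  # [1.07, 1.17) misses

    def test_half_open_boundary(self):
        on = np.zeros(5000, dtype=bool)
        on[999] = True  # burst ends one sample before window start at 1.0 s
        d = SlidingWindowDesign(0.0, 0.2, 0.1, 0.01)
        lab = window_stim_labels(on, RATE, np.array([1.0]), d)
        assert not lab.labels[0, 0]
        on[1000] = True
        lab = window_stim_labels(on, RATE, np.array([1.0]), d)
        assert lab.labels[0, 0]

    def test_matches_brute_force_overlap_oracle(self, schedule):
        n = int(schedule.duration * RATE)
        on = schedule.suprathreshold(RATE, n)
        events = np.arange(5.0, 350.0, 7.1)
        d = SlidingWindowDesign.feedback()
        lab = window_stim_labels(on, RATE, events, d)
        for k in range(0, events.size, 9):
            for w in range(0, d.n_windows, 23):
                t0 = events[k] + d.starts[w]
                i0 = int(np.ceil(t0 * RATE - 1e-9))
                i1 = int(np.ceil((t0 + d.length) * RATE - 1e-9))
                assert lab.labels[k, w] == on[i0:i1].any()

    def test_on_fraction_stable_across_alignments(self, schedule):
        n = int(schedule.duration * RATE)
        on = schedule.suprathreshold(RATE, n)
        ev1 = np.arange(5.0, 350.0, 6.3)
        ev2 = np.arange(7.2, 350.0, 6.7)
        f1 = window_stim_labels(on, RATE, ev1, SlidingWindowDesign.feedback()).on_fraction()
        f2 = window_stim_labels(on, RATE, ev2, SlidingWindowDesign.movement()).on_fraction()
        assert f1.mean() == pytest.approx(f2.mean(), abs=0.05)


class TestBehaviorContrast:
    def test_injected_window_effect_recovered(self, rng):
        # burst-like labels: one contiguous ON run per trial
        n_sub, m, W = 8, 60, 40
        centers = rng.uniform(-10, W + 10, size=n_sub * m)
        w_idx = np.arange(W)
        labels = np.abs(w_idx[None, :] - centers[:, None]) < 10
        beh = rng.normal(2.0, 1.0, size=n_sub * m)
        boost = 10  # stimulation overlapping windows 10-14 boosts behavior
        affected = labels[:, boost : boost + 5].any(axis=1)
        beh = beh + 1.5 * affected
        subj = np.repeat(np.arange(n_sub), m)
        d = SlidingWindowDesign(0.0, 0.49, 0.1, 0.01)
        diffs, ids = stim_behavior_contrast(
            StimWindowLabels(labels, np.arange(n_sub * m), "value_cue", d),
            beh, subj,
        )
        assert diffs.shape == (n_sub, W)
        res = cluster_permutation_labels(diffs, d, n_perm=200, seed=0)
        sig = [c for c in res.clusters if c["p"] <= 0.05]
        assert any(c["start"] < boost + 5 and c["stop"] > boost for c in sig)

    def test_identity_permutation_reproduces_observed(self, rng):
        diffs = rng.normal(size=(6, 30))
        t_obs, _ = group_t_series(diffs)
        res = cluster_permutation_labels(diffs, SlidingWindowDesign(0, 0.39, 0.1, 0.01),
                                         n_perm=100, seed=1)
        assert np.allclose(res.tvalues, t_obs, equal_nan=True)
        # all-plus flip is the identity: the observed t must be attainable
        flipped, _ = group_t_series(diffs * 1.0)
        assert np.allclose(flipped, t_obs)

    def test_subject_missing_condition_dropped_per_window(self, rng):
        labels = np.zeros((40, 10), dtype=bool)
        labels[:20, :5] = rng.random((20, 5)) < 0.5
        # second subject never stimulated -> NaN in every window
        beh = rng.normal(size=40)
        subj = np.repeat(["a", "b"], 20)
        d = SlidingWindowDesign(0.0, 0.19, 0.1, 0.01)
        diffs, ids = stim_behavior_contrast(
            StimWindowLabels(labels, np.arange(40), "value_cue", d), beh, subj
        )
        assert np.isnan(diffs[1]).all()
        assert np.isnan(diffs[0, 5:]).all()
        assert np.isfinite(diffs[0, :5]).any()

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_permutation_labels(rng.normal(size=(3, 10)),
                                       SlidingWindowDesign(0, 0.19, 0.1, 0.01))


class TestStimAlignedBeta:
    def test_no_suppression_stays_at_unity(self, rng):
        sch = generate_dbs_schedule(StimScheduleConfig(seed=2), 300.0)
        times = np.arange(0, 300.0, 0.02)
        beta = rng.lognormal(0, 0.2, size=times.size)
        epochs, rel, durs = stim_aligned_beta(beta, times, sch)
        assert epochs.mean() == pytest.approx(1.0, abs=0.05)

    def test_known_suppression_recovered(self):
        sch = generate_dbs_schedule(StimScheduleConfig(seed=3), 300.0)
        times = np.arange(0, 300.0, 0.02)
        beta = np.ones(times.size)
        g = 0.4
        for _, p0, p1, _ in sch.segments:
            beta[(times >= p0) & (times < p1)] = 1.0 - g
        epochs, rel, durs = stim_aligned_beta(beta, times, sch)
        sel = (rel >= 0.05) & (rel < 0.12)
        assert 1.0 - epochs[:, sel].mean() == pytest.approx(g, abs=0.05)

    def test_empty_schedule_rejected(self):
        sch = StimSchedule(np.empty((0, 4)), 10.0)
        with pytest.raises(ValueError):
            stim_aligned_beta(np.ones(500), np.arange(500) * 0.02, sch)


class TestWindowedContrastAndConditionals:
    def test_identical_conditions_yield_no_cluster(self, rng):
        beta = rng.normal(1.0, 0.3, size=(300, 25))
        on_a = rng.random(300) < 0.5
        on_b = rng.random(300) < 0.5
        subj = np.repeat(np.arange(6), 50)
        res = windowed_beta_contrast(beta, on_a, on_b, subj,
                                     SlidingWindowDesign(0, 0.34, 0.1, 0.01),
                                     n_perm=200, seed=4)
        assert not [c for c in res.clusters if c["p"] <= 0.05]

    def test_window_specific_suppression_detected(self, rng):
        beta = rng.normal(1.0, 0.3, size=(600, 25))
        on_a = rng.random(600) < 0.5
        on_b = rng.random(600) < 0.5
        beta[on_a & ~on_b, 8:16] -= 0.5
        subj = np.repeat(np.arange(6), 100)
        res = windowed_beta_contrast(beta, on_a, on_b, subj,
                                     SlidingWindowDesign(0, 0.34, 0.1, 0.01),
                                     n_perm=200, seed=4)
        sig = [c for c in res.clusters if c["p"] <= 0.05 and c["sign"] < 0]
        assert any(c["start"] < 16 and c["stop"] > 8 for c in sig)

    def test_symmetric_strata_show_no_difference(self, rng):
        n = 600
        stim_on = rng.random(n) < 0.5
        beh = rng.normal(2, 1, size=n) + 1.0 * stim_on
        strata = rng.random(n) < 0.5
        subj = np.repeat(np.arange(6), 100)
        res = conditional_effects(stim_on, beh, strata, subj)
        assert res["paired_p"] > 0.01
        # the window effect itself is present in both strata
        for lev in res["stratum_tests"].values():
            assert lev["mean"] > 0.5

    def test_degenerate_strata_flagged(self, rng):
        n = 200
        stim_on = rng.random(n) < 0.5
        beh = rng.normal(size=n)
        subj = np.repeat(["a", "b", "c", "d"], 50)
        with pytest.raises(ValueError, match="two strata"):
            conditional_effects(stim_on, beh, np.ones(n, dtype=bool), subj)
        strata = rng.random(n) < 0.5
        strata[150:] = True  # subject d never contributes stratum False
        res = conditional_effects(stim_on, beh, strata, subj)
        assert res["degenerate_subjects"] == 1
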