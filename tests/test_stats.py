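"""Sliding-window inference: z-scoring, cluster permutation, per-subject
regression, BIC."""

import numpy as np
import pytest
from scipy import stats as sps

from stnadapt.lme import fit_random_intercept
from stnadapt.stats import (
    SlidingWindowDesign,
    bic,
    cluster_permutation_trials,
    compare_bic,
    evidence_label,
    find_clusters,
    per_subject_regression,
    sliding_lme,
    window_means,
    zscore_and_prune,
)


class TestWindows:
    def test_feedback_grid_has_191_windows(self):
        assert SlidingWindowDesign.feedback().n_windows == 191

    def test_movement_grid_has_91_windows(self):
        assert SlidingWindowDesign.movement().n_windows == 91

    def test_window_means_on_known_series(self):
        times = np.arange(0, 2.01, 0.02)
        vals = np.tile(times, (3, 1))  # value equals its own time stamp
        d = SlidingWindowDesign(0.0, 2.0)
        out = window_means(vals, times, d)
        expected = [times[(times >= t - 1e-9) & (times < t + 0.1 - 1e-9)].mean()
                    for t in d.starts]
        assert np.allclose(out[0], expected, atol=1e-9)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            SlidingWindowDesign(0.0, 2.0, length=0.1, step=0.2)


class TestZscore:
    def test_mean_zero_unit_sd_per_subject(self, rng):
        vals = rng.normal(5, 2, size=(60, 10))
        subj = np.repeat(["a", "b", "c"], 20)
        z, keep = zscore_and_prune(vals, subj)
        for s in "abc":
            block = z[subj == s]
            assert block[keep[subj == s]].mean() == pytest.approx(0.0, abs=0.2)
            assert block[np.isfinite(block[:, 0])].std() == pytest.approx(1.0, abs=0.1)

    def test_extreme_trial_excluded(self, rng):
        vals = rng.normal(0, 1, size=(40, 8))
        vals[7] += 25.0
        z, keep = zscore_and_prune(vals, np.repeat("s", 40))
        assert not keep[7]
        assert np.isnan(z[7]).all()

    def test_exclusion_fraction_small_on_default_cohort(self, rng):
        # Gaussian trials rarely exceed an epoch-mean |z| of 3
        vals = rng.normal(0, 1, size=(400, 20))
        _, keep = zscore_and_prune(vals, np.repeat(["a", "b"], 200))
        assert 1.0 - keep.mean() < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_and_prune(np.ones((20, 4)), np.repeat("s", 20))


def _coupled_data(seed, n_sub=5, m=40, W=30, effect=0.0, lo=10, hi=18):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_sub), m)
    x1 = rng.normal(size=subj.size)
    x2 = rng.normal(size=subj.size)
    Y = rng.normal(size=(subj.size, W))
    Y[:, lo:hi] += effect * x1[:, None]
    return Y, np.column_stack([x1, x2]), subj


class TestClusterPermutation:
    def test_unshuffled_fit_reproduces_observed_t(self):
        Y, X, subj = _coupled_data(1, effect=0.5)
        t_direct, _ = sliding_lme(Y, X, subj)
        res = cluster_permutation_trials(Y, X, subj,
                                         SlidingWindowDesign(0, 0.4, 0.1, 0.01),
                                         n_perm=100, seed=0)
        assert np.allclose(res[0].tvalues, t_direct[0], equal_nan=True)

    def test_injected_effect_found_with_correct_sign_and_location(self):
        Y, X, subj = _coupled_data(2, effect=0.8)
        res = cluster_permutation_trials(Y, X, subj,
                                         SlidingWindowDesign(0, 0.4, 0.1, 0.01),
                                         n_perm=200, seed=0)
        sig = [c for c in res[0].clusters if c["p"] <= 0.05]
        assert len(sig) == 1
        assert sig[0]["sign"] == 1
        assert sig[0]["start"] <= 10 < 18 <= sig[0]["stop"] + 8
        assert not [c for c in res[1].clusters if c["p"] <= 0.05]

    def test_negated_data_mirrors_clusters(self):
        Y, X, subj = _coupled_data(3, effect=0.8)
        d = SlidingWindowDesign(0, 0.4, 0.1, 0.01)
        r_pos = cluster_permutation_trials(Y, X, subj, d, n_perm=100, seed=5)
        r_neg = cluster_permutation_trials(-Y, X, subj, d, n_perm=100, seed=5)
        assert np.allclose(r_pos[0].tvalues, -r_neg[0].tvalues, atol=1e-8)
        pos = [(c["start"], c["stop"], c["mass"]) for c in r_pos[0].clusters]
        neg = [(c["start"], c["stop"], c["mass"]) for c in r_neg[0].clusters]
        assert pos == neg

    def test_null_pvalues_are_valid(self):
        # under the null, P(p <= alpha) should not exceed alpha by much
        hits = {0.05: 0, 0.1: 0}
        n_sim = 40
        for k in range(n_sim):
            Y, X, subj = _coupled_data(100 + k, W=25)
            res = cluster_permutation_trials(
                Y, X, subj, SlidingWindowDesign(0, 0.34, 0.1, 0.01),
                n_perm=99, seed=k,
            )
            pmin = min((c["p"] for r in res for c in r.clusters), default=1.0)
            for a in hits:
                hits[a] += pmin <= a
        assert hits[0.05] / n_sim <= 0.175
        assert hits[0.1] / n_sim <= 0.25

    def test_low_permutation_count_warns(self):
        Y, X, subj = _coupled_data(4)
        with pytest.warns(UserWarning, match="low"):
            cluster_permutation_trials(Y, X, subj,
                                       SlidingWindowDesign(0, 0.4, 0.1, 0.01),
                                       n_perm=50, seed=0)


class TestFindClusters:
    def test_runs_and_masses(self):
        t = np.array([0.0, 3.0, 3.5, 0.0, -4.0, -4.5, 1.0])
        cl = find_clusters(t, 2.0)
        assert len(cl) == 2
        assert cl[0] == dict(start=1, stop=3, sign=1, mass=pytest.approx(6.5))
        assert cl[1] == dict(start=4, stop=6, sign=-1, mass=pytest.approx(8.5))

    def test_nan_breaks_runs(self):
        t = np.array([3.0, np.nan, 3.0])
        cl = find_clusters(t, 2.0)
        assert [(c["start"], c["stop"]) for c in cl] == [(0, 1), (2, 3)]


class TestPerSubjectRegression:
    def test_zero_correlation_gives_zero_fisher_z(self, rng):
        subj = np.repeat(np.arange(6), 30)
        x = np.tile(np.linspace(-1, 1, 30), 6)
        y = rng.normal(size=subj.size)
        res = per_subject_regression(y, x, subj)
        assert np.abs(res.fisher_z).max() < 0.5
        assert res.pvalue > 0.01

    def test_consistent_effect_detected_and_sign_matches_lme(self, rng):
        subj = np.repeat(np.arange(6), 40)
        x = rng.normal(size=subj.size)
        y = 0.8 * x + rng.normal(size=subj.size)
        res = per_subject_regression(y, x, subj)
        assert res.tstat > 0 and res.pvalue < 0.01
        lme = fit_random_intercept(
            np.column_stack([np.ones_like(x), x]), y, subj
        )
        assert np.sign(lme.params[1]) == np.sign(res.tstat)

    def test_small_subject_excluded_with_warning(self, rng):
        subj = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30 + ["d"] * 3)
        x = rng.normal(size=subj.size)
        y = rng.normal(size=subj.size)
        with pytest.warns(UserWarning, match="excluded"):
            res = per_subject_regression(y, x, subj)
        assert res.n_subjects == 3 and res.excluded == ["d"]


class TestBic:
    def test_closed_form_on_ten_observations(self):
        rng = np.random.default_rng(0)
        g = np.repeat([0, 1], 5)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = rng.normal(size=10)
        fit = fit_random_intercept(X, y, g)
        k = 2 + 2  # fixed effects + two variance components
        assert bic(fit.loglik, k, 10) == pytest.approx(
            k * np.log(10) - 2 * fit.loglik
        )

    def test_duplicate_model_has_zero_delta(self):
        rng = np.random.default_rng(1)
        g = np.repeat(np.arange(4), 20)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = X @ [1.0, 0.5] + rng.normal(size=80)
        fit = fit_random_intercept(X, y, g)
        table = compare_bic({"a": fit, "b": fit})
        assert table["delta_bic"].tolist() == [0.0, 0.0]
        assert table["evidence"].iloc[1] == "inconclusive"

    def test_noise_predictor_penalized(self):
        rng = np.random.default_rng(2)
        g = np.repeat(np.arange(6), 40)
        x = rng.normal(size=240)
        noise = rng.normal(size=240)
        y = 0.7 * x + rng.normal(size=240) + rng.normal(size=6)[g]
        X1 = np.column_stack([np.ones(240), x])
        X2 = np.column_stack([X1, noise])
        f1 = fit_random_intercept(X1, y, g)
        f2 = fit_random_intercept(X2, y, g)
        table = compare_bic({"base": f1, "with_noise": f2})
        assert table.loc["base", "bic"] < table.loc["with_noise", "bic"]

    def test_differing_observation_sets_rejected(self):
        rng = np.random.default_rng(3)
        g = np.repeat([0, 1, 2], 20)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = rng.normal(size=60)
        f1 = fit_random_intercept(X, y, g)
        f2 = fit_random_intercept(X[:40], y[:40], g[:40])
        with pytest.raises(ValueError, match="observation"):
            compare_bic({"a": f1, "b": f2})

    def test_evidence_labels(self):
        assert evidence_label(1.0) == "inconclusive"
        assert evidence_label(3.0) == "positive"
        assert evidence_label(-7.0) == "strong"
        assert evidence_label(12.0) == "very strong"
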