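from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accelcal.calibrate import (
    CalibrationError,
    CrossingThresholdsError,
    EmptyPredictedClassError,
    fit_cumulative_logit,
    kmeans_calibrate,
    olr_calibrate,
    predict_class_probs,
    roc_calibrate,
    roc_threshold,
    summarize_classes,
)
from accelcal.cutpoints import BUTTE_HIP, CutPointSet, label_series


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_roc(w, pos):
    """Naive per-threshold loop: positive predicted when w > t."""
    best = None
    n_pos, n_neg = pos.sum(), (~pos).sum()
    for t in np.unique(w):
        sens = ((w > t) & pos).sum() / n_pos
        spec = ((w <= t) & ~pos).sum() / n_neg
        d = abs(sens - spec)
        if best is None or d < best[0] - 1e-12:
            best = (d, int(t), sens, spec)
    return best[1:]


def exhaustive_kmeans_wcss(values, k):
    """Minimum WCSS over all contiguous k-partitions of the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def sse(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    for splits in combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        wcss = sum(sse(v[a:b]) for a, b in zip(bounds, bounds[1:]))
        best = min(best, wcss)
    return best


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfectly_separated_dichotomy(self):
        w = np.array([100, 200, 1000, 1100])
        pos = np.array([False, False, True, True])
        t, sens, spec = roc_threshold(w, pos)
        assert (t, sens, spec) == (200, 1.0, 1.0)

    def test_threshold_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(10, 200)
            w = rng.integers(0, 500, n)
            pos = rng.random(n) < 0.4
            if pos.all() or not pos.any() or np.unique(w).size < 2:
                continue
            t, sens, spec = roc_threshold(w, pos)
            bt, bsens, bspec = brute_force_roc(w, pos)
            assert t == bt and sens == pytest.approx(bsens) and spec == pytest.approx(bspec)

    def test_recovers_partition_of_existing_cut_set(self, pure_training_data):
        w, labels = pure_training_data
        res = roc_calibrate(w, labels)
        assert np.array_equal(label_series(w, res.cuts), labels)

    def test_constant_counts_rejected(self):
        y = np.array([0, 1, 2, 3] * 3)
        with pytest.raises(CalibrationError, match="separates"):
            roc_calibrate(np.full(12, 7), y)

    def test_crossing_thresholds_reported(self):
        # VPA counts placed *below* SB counts make the three dichotomies cross
        w = np.array([100, 110, 50, 60, 70, 80, 10, 20])
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        with pytest.raises(CrossingThresholdsError, match="crossing|increase"):
            roc_calibrate(w, y)

    def test_missing_class_rejected(self):
        with pytest.raises(CalibrationError, match="missing"):
            roc_calibrate(np.arange(6), np.array([0, 0, 1, 1, 2, 2]))

    def test_permutation_invariance(self, noisy_training_data):
        w, labels = noisy_training_data
        res = roc_calibrate(w, labels)
        perm = np.random.default_rng(1).permutation(len(w))
        res_p = roc_calibrate(w[perm], labels[perm])
        assert res.cuts == res_p.cuts


# ---------------------------------------------------------------------------
# Ordinal cumulative-logit regression
# ---------------------------------------------------------------------------

def sample_cumlogit(alpha, beta, x, rng):
    cdf = 1 / (1 + np.exp(-(np.asarray(alpha)[None, :] - beta * x[:, None])))
    u = rng.random(len(x))[:, None]
    return (u > cdf).sum(axis=1)


class TestOlr:
    def test_class_probabilities_at_known_parameters(self):
        probs = predict_class_probs(np.array([0.0]), np.array([0.0, 2.0, 4.0]), 1.0)[0]
        assert probs[0] == pytest.approx(0.5, abs=1e-6)
        assert probs[1] == pytest.approx(0.3808, abs=1e-3)
        assert np.argmax(probs) == 0

    def test_parameter_recovery_against_statsmodels(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 4000)
        alpha, beta = np.array([2.0, 4.0, 6.0]), 1.0
        y = sample_cumlogit(alpha, beta, x, rng)
        fit = fit_cumulative_logit(x, y, ridge=0.0)

        sm_res = OrderedModel(y, x[:, None], distr="logit").fit(disp=False)
        sm_beta = sm_res.params[0]
        sm_alpha = sm_res.model.transform_threshold_params(sm_res.params)[1:-1]
        # agreement with the independent MLE ...
        assert fit["beta"] == pytest.approx(sm_beta, abs=1e-3)
        np.testing.assert_allclose(fit["alpha"], sm_alpha, atol=5e-3)
        # ... and with the truth, within 3 standard errors
        assert abs(fit["beta"] - beta) < 3 * sm_res.bse[0]
        assert abs(fit["alpha"][0] - alpha[0]) < 3 * sm_res.bse[1]

    def test_argmax_classes_are_contiguous_intervals(self, noisy_training_data):
        w, labels = noisy_training_data
        res = olr_calibrate(w, labels)
        fit = res.diagnostics["fit"]
        grid = np.arange(0, int(w.max()) + 1, 7)
        assigned = np.argmax(predict_class_probs(grid.astype(float), fit["alpha"], fit["beta"]), axis=1)
        assert np.all(np.diff(assigned) >= 0)

    def test_cut_points_follow_max_min_rule(self, noisy_training_data):
        w, labels = noisy_training_data
        res = olr_calibrate(w, labels)
        fit = res.diagnostics["fit"]
        assigned = np.argmax(predict_class_probs(w.astype(float), fit["alpha"], fit["beta"]), axis=1)
        assert res.cuts.t1 == w[assigned == 0].max()
        assert res.cuts.t2 == w[assigned == 2].min() - 1
        assert res.cuts.t3 == w[assigned == 3].min() - 1

    def test_empty_predicted_class_is_reported(self):
        # a nearly-empty, fully overlapped MPA class never wins the argmax
        rng = np.random.default_rng(3)
        w = np.concatenate(
            [
                rng.integers(0, 1000, 400),
                rng.integers(1000, 3000, 400),
                rng.integers(0, 4000, 5),
                rng.integers(3000, 4000, 200),
            ]
        )
        y = np.concatenate([np.zeros(400), np.ones(400), np.full(5, 2), np.full(200, 3)]).astype(int)
        with pytest.raises(EmptyPredictedClassError, match="MPA"):
            olr_calibrate(w, y)

    def test_constant_predictor_rejected(self):
        y = np.array([0, 1, 2, 3] * 3)
        with pytest.raises(CalibrationError, match="constant"):
            olr_calibrate(np.full(12, 5), y)

    def test_permutation_invariance(self, noisy_training_data):
        w, labels = noisy_training_data
        res = olr_calibrate(w, labels)
        perm = np.random.default_rng(2).permutation(len(w))
        res_p = olr_calibrate(w[perm], labels[perm])
        assert res.cuts == res_p.cuts


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

class TestKmeans:
    def test_well_separated_quadruplets(self):
        res = kmeans_calibrate([1, 2, 10, 11, 20, 21, 30, 31])
        assert (res.cuts.t1, res.cuts.t2, res.cuts.t3) == (2, 11, 21)
        assert res.diagnostics["wcss"] == pytest.approx(4 * 0.5)

    def test_singleton_clusters_reach_zero_wcss(self):
        res = kmeans_calibrate([0, 0, 0, 0, 1, 2, 3])
        assert res.diagnostics["wcss"] == pytest.approx(0.0, abs=1e-12)
        assert (res.cuts.t1, res.cuts.t2, res.cuts.t3) == (0, 1, 2)

    def test_dp_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(4, 13)
            vals = rng.integers(0, 40, n)
            if np.unique(vals).size < 4:
                continue
            res = kmeans_calibrate(vals)
            assert res.diagnostics["wcss"] == pytest.approx(
                exhaustive_kmeans_wcss(vals, 4), abs=1e-9
            )

    def test_lloyd_never_beats_dp(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            vals = rng.integers(0, 2000, 300)
            dp = kmeans_calibrate(vals, method="dp")
            lloyd = kmeans_calibrate(vals, method="lloyd", seed=seed)
            assert lloyd.diagnostics["wcss"] >= dp.diagnostics["wcss"] - 1e-6

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(CalibrationError, match="distinct"):
            kmeans_calibrate([1, 1, 2, 2, 3, 3])

    def test_ties_stay_in_one_cluster(self):
        # duplicated boundary values cannot straddle a DP cluster boundary
        vals = np.array([1, 1, 5, 5, 5, 9, 9, 13, 13])
        res = kmeans_calibrate(vals)
        assigned = label_series(vals, res.cuts)
        for v in np.unique(vals):
            assert np.unique(assigned[vals == v]).size == 1

    def test_permutation_invariance(self, noisy_training_data):
        w, _ = noisy_training_data
        res = kmeans_calibrate(w)
        perm = np.random.default_rng(6).permutation(len(w))
        assert kmeans_calibrate(w[perm]).cuts == res.cuts


# ---------------------------------------------------------------------------
# per-class summaries
# ---------------------------------------------------------------------------

class TestSummarizeClasses:
    def test_mean_and_sample_sd(self):
        df = summarize_classes([1.0, 3.0], [0, 0])
        row = df.iloc[0]
        assert row["n"] == 2 and row["mean"] == 2.0
        assert row["sd"] == pytest.approx(np.sqrt(2))

    def test_singleton_class_sd_undefined(self):
        df = summarize_classes([5.0], [2])
        assert df.iloc[2]["n"] == 1 and np.isnan(df.iloc[2]["sd"])
        assert df.iloc[0]["n"] == 0 and np.isnan(df.iloc[0]["mean"])

    def test_class_means_increase_for_calibration_results(self, noisy_training_data):
        w, labels = noisy_training_data
        for res in (roc_calibrate(w, labels), kmeans_calibrate(w), olr_calibrate(w, labels)):
            means = res.per_class["mean"].dropna().to_numpy()
            assert np.all(np.diff(means) > 0)
            assert res.per_class["n"].sum() == len(w)
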