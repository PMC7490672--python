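import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accelcal.validate import (
    agreement_report,
    cohen_kappa,
    compare_methods,
    confusion,
    daily_time,
    estimate_table,
    one_vs_rest_metrics,
    overall_agreement,
    summarize_tally,
)


class TestConfusion:
    def test_identical_sequences_are_diagonal(self):
        m = confusion([0, 1, 2, 3, 3], [0, 1, 2, 3, 3])
        assert np.array_equal(m, np.diag([1, 1, 1, 2]))

    def test_pair_counts(self):
        m = confusion([0, 0, 1], [0, 1, 1])
        assert m[0, 0] == 1 and m[0, 1] == 1 and m[1, 1] == 1 and m.sum() == 3

    def test_empty_input_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="empty"):
            m = confusion([], [])
        assert m.shape == (4, 4) and m.sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion([0, 1], [0])


class TestOneVsRest:
    def test_perfect_agreement(self):
        m = np.diag([10, 10, 10, 10])
        met = one_vs_rest_metrics(m, 0)
        assert (met["sensitivity"], met["specificity"]) == (100.0, 100.0)
        assert (met["fpr"], met["fnr"]) == (0.0, 0.0)

    def test_two_by_two_formula(self):
        m = np.array([[45, 15], [25, 15]])
        met = one_vs_rest_metrics(m, 0)
        assert met["sensitivity"] == pytest.approx(75.0)
        assert met["specificity"] == pytest.approx(37.5)

    def test_absent_reference_class_is_undefined(self):
        m = np.zeros((4, 4), dtype=int)
        m[1, 1] = 5
        met = one_vs_rest_metrics(m, 0)
        assert np.isnan(met["sensitivity"]) and np.isnan(met["fnr"])

    @given(
        st.lists(st.integers(0, 50), min_size=16, max_size=16),
        st.integers(0, 3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_complement_identities(self, cells, cls):
        m = np.array(cells).reshape(4, 4)
        met = one_vs_rest_metrics(m, cls)
        if np.isfinite(met["specificity"]):
            assert met["fpr"] == pytest.approx(100.0 - met["specificity"])
        if np.isfinite(met["sensitivity"]):
            assert met["fnr"] == pytest.approx(100.0 - met["sensitivity"])


class TestCohenKappa:
    def test_identical_labelings(self):
        assert cohen_kappa([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_binarized_hand_example(self):
        # confusion [[45,15],[25,15]]: p_o = 0.60, p_e = 0.54, kappa = 0.1304
        ref = np.repeat([0, 0, 1, 1], [45, 15, 25, 15])
        comp = np.repeat([0, 1, 0, 1], [45, 15, 25, 15])
        assert cohen_kappa(ref, comp) == pytest.approx(0.06 / 0.46, abs=1e-10)

    def test_independent_labelings_have_zero_kappa(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 4, 100_000), rng.integers(0, 4, 100_000)
        assert cohen_kappa(a, b) == pytest.approx(0.0, abs=0.01)

    def test_constant_equal_labelings_undefined(self):
        assert np.isnan(cohen_kappa([1, 1, 1], [1, 1, 1], 4))

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 4, 500)
            b = np.where(rng.random(500) < 0.6, a, rng.integers(0, 4, 500))
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestOverallAgreement:
    def test_diagonal_and_uniform(self):
        assert overall_agreement(np.diag([3, 3, 3, 3])) == 100.0
        assert overall_agreement(np.full((4, 4), 5)) == 25.0

    def test_printed_scale(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 0] = 7151
        m[0, 1] = 10000 - 7151
        assert overall_agreement(m) == pytest.approx(71.51)

    def test_empty_matrix_undefined(self):
        assert np.isnan(overall_agreement(np.zeros((4, 4))))


class TestAgreementReport:
    def test_grouping_mvpa_never_decreases_accuracy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ref = rng.integers(0, 4, 2000)
            comp = np.where(rng.random(2000) < 0.5, ref, rng.integers(0, 4, 2000))
            rep = agreement_report(ref, comp, "x")
            assert rep.grouped_accuracy >= rep.overall_accuracy - 1e-9

    def test_matrix_totals_reconcile(self):
        rng = np.random.default_rng(3)
        ref, comp = rng.integers(0, 4, 500), rng.integers(0, 4, 500)
        rep = agreement_report(ref, comp, "x")
        assert rep.matrix.sum() == 500 and rep.matrix_grouped.sum() == 500


class TestDailyTime:
    def test_full_sedentary_day(self):
        mins = daily_time(np.zeros(1200, dtype=int), 15)
        assert mins["SB"] == 300 and mins["wear"] == 300 and mins["MVPA"] == 0

    def test_empty_day(self):
        mins = daily_time(np.array([], dtype=int), 15)
        assert all(mins[k] == 0 for k in ("SB", "LPA", "MPA", "VPA", "wear"))

    def test_partition_of_wear_time(self):
        rng = np.random.default_rng(4)
        lab = rng.integers(0, 4, 700)
        mins = daily_time(lab, 15)
        assert mins["SB"] + mins["LPA"] + mins["MPA"] + mins["VPA"] == pytest.approx(
            mins["wear"]
        )

    def test_additive_over_concatenated_days(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(0, 4, 300), rng.integers(0, 4, 500)
        whole = daily_time(np.concatenate([a, b]), 15)
        parts = daily_time(a, 15), daily_time(b, 15)
        for k in ("SB", "LPA", "MPA", "VPA", "MVPA", "wear"):
            assert whole[k] == pytest.approx(parts[0][k] + parts[1][k])


def label_frame(day_labels):
    rows = []
    for (pid, day, method), labels in day_labels.items():
        for lab in labels:
            rows.append({"participant_id": pid, "day": day, "method": method, "label": lab})
    return pd.DataFrame(rows)


class TestEstimateTable:
    def test_single_day_sd_undefined(self):
        df = estimate_table(label_frame({("A", 0, "hip"): [0, 0, 1, 2]}), 15)
        assert np.isnan(df["sd_minutes"]).all()
        assert df[df["class"] == "SB"]["mean_minutes"].iloc[0] == pytest.approx(0.5)

    def test_identical_days_have_zero_sd(self):
        df = estimate_table(
            label_frame({("A", 0, "hip"): [0, 1, 2, 3], ("A", 1, "hip"): [0, 1, 2, 3]}), 15
        )
        assert (df["sd_minutes"] == 0).all()

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(6)
        frames = {
            ("A", d, "hip"): rng.integers(0, 4, 240).tolist() for d in range(3)
        }
        df = estimate_table(label_frame(frames), 15)
        four = df[df["class"].isin(["SB", "LPA", "MPA", "VPA"])]
        assert four["pct_of_wear"].sum() == pytest.approx(100.0, abs=0.1)


class TestCompareMethods:
    def test_method_against_itself_is_exactly_zero(self):
        frames = {
            ("A", d, m): [0, 1, 2, 3] * 5
            for d in range(3)
            for m in ("hip", "hip2")
        }
        out = compare_methods(label_frame(frames), "hip", "hip2", "SB", 15, seed=0)
        assert out["mean_difference"] == 0.0
        assert (out["ci_low"], out["ci_high"]) == (0.0, 0.0)
        assert out["no_difference"]

    def test_constant_offset_detected(self):
        frames = {}
        for d in range(10):
            frames[("A", d, "hip")] = [0] * 40 + [1] * 40
            frames[("A", d, "comp")] = [0] * 80  # +10 min SB every day
        out = compare_methods(label_frame(frames), "hip", "comp", "SB", 15, seed=0)
        assert out["mean_difference"] == pytest.approx(10.0)
        assert out["ci_low"] > 0 and not out["no_difference"]

    def test_bootstrap_interval_covers_null_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            frames = {}
            for d in range(15):
                k_a, k_b = rng.binomial(60, 0.5), rng.binomial(60, 0.5)
                frames[("A", d, "a")] = [0] * k_a + [1] * (60 - k_a)
                frames[("A", d, "b")] = [0] * k_b + [1] * (60 - k_b)
            out = compare_methods(
                label_frame(frames), "a", "b", "SB", 15, n_boot=400, seed=int(rng.integers(2**31))
            )
            covered += out["no_difference"]
        assert 0.85 <= covered / n_rep <= 1.0

    def test_too_few_pairs_rejected(self):
        frames = {("A", 0, "a"): [0], ("A", 0, "b"): [0]}
        with pytest.raises(ValueError, match="paired"):
            compare_methods(label_frame(frames), "a", "b", "SB", 15)


class TestSummarizeTally:
    def test_partition_percentages(self):
        out = summarize_tally([25, 25, 25, 25])
        assert out["total"] == 100 and out["mvpa"] == 50
        assert all(v == 25.0 for v in out["percent"].values())

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            summarize_tally([1, 2, 3])
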