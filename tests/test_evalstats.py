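"""Evaluation battery: correlations, t-tests, thresholds, dispersion, Pareto."""

import numpy as np
import pytest
from scipy import stats

from neuroscore import (
    binary_threshold_metrics,
    correlation_with_stage,
    dispersion_table,
    evaluate_scores,
    pairwise_ttests,
    pareto_bins,
    threeclass_threshold_metrics,
)
from neuroscore.evalstats import (
    UndefinedStatisticError,
    _binary_counts,
    _candidate_thresholds,
    _predict_threeclass,
)


def random_staged_scores(rng, n, means=(80.0, 60.0, 40.0), sd=10.0):
    stages = rng.choice(["NC", "MCI", "AD"], size=n)
    mean_by = dict(zip(["NC", "MCI", "AD"], means))
    scores = np.array([rng.normal(mean_by[s], sd) for s in stages])
    return scores, stages


class TestCorrelation:
    def test_perfect_anti_monotone(self):
        res = correlation_with_stage([3, 2, 1], ["NC", "MCI", "AD"])
        assert res.pearson == pytest.approx(-1.0)
        assert res.spearman == pytest.approx(-1.0)

    def test_identity_coding(self):
        res = correlation_with_stage([0, 1, 1, 2], ["NC", "MCI", "MCI", "AD"])
        assert res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)

    def test_spearman_with_ties_matches_midrank_oracle(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0])
        stages = ["NC", "MCI", "MCI", "AD"]
        res = correlation_with_stage(scores, stages)
        # oracle: midranks then plain Pearson
        ranks_s = stats.rankdata(scores)
        ranks_c = stats.rankdata([0, 1, 1, 2])
        expected = stats.pearsonr(ranks_s, ranks_c).statistic
        assert res.spearman == pytest.approx(expected, abs=1e-12)

    def test_percent_display_values(self):
        res = correlation_with_stage([3, 2, 1], ["NC", "MCI", "AD"])
        assert res.pearson_abs_pct == pytest.approx(100.0)

    def test_constant_scores_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlation_with_stage([1, 1, 1], ["NC", "MCI", "AD"])

    def test_single_stage_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlation_with_stage([1, 2, 3], ["NC", "NC", "NC"])


class TestTTests:
    def _stages(self, na, nb, nc):
        return np.array(["NC"] * na + ["MCI"] * nb + ["AD"] * nc)

    def test_identical_groups_pooled_p_is_1(self):
        scores = np.array([1.0, 2.0, 3.0] * 3)
        out = pairwise_ttests(scores, self._stages(3, 3, 3), equal_var=True)
        for pair in out:
            assert out[pair]["t"] == pytest.approx(0.0, abs=1e-12)
            assert out[pair]["p"] == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        eps = 1e-6
        scores = np.concatenate([[0, 0, 0, eps], [10, 10, 10, 10 + eps],
                                 [20, 20, 20, 20 + eps]])
        out = pairwise_ttests(scores, self._stages(4, 4, 4))
        # oracle: evaluate the Welch t CDF directly
        ga, gb = scores[:4], scores[4:8]
        t, p = stats.ttest_ind(ga, gb, equal_var=False)
        assert out["NC/MCI"]["p"] == pytest.approx(p)
        assert out["NC/MCI"]["p"] < 1e-6

    def test_symmetry_under_group_swap(self, rng):
        scores, stages = random_staged_scores(rng, 60)
        out = pairwise_ttests(scores, stages)
        swapped = np.where(stages == "NC", "AD",
                           np.where(stages == "AD", "NC", stages))
        out2 = pairwise_ttests(scores, swapped)
        assert out["NC/AD"]["p"] == pytest.approx(out2["NC/AD"]["p"])

    def test_small_group_rejected_by_name(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stages = np.array(["NC", "NC", "MCI", "MCI", "AD"])
        with pytest.raises(ValueError, match="AD"):
            pairwise_ttests(scores, stages)


def brute_force_binary(scores, stages, pos_stage, low_is_pos):
    """Exhaustive scan over all candidate thresholds (independent oracle)."""
    best = None
    is_pos = stages == pos_stage
    for thr in _candidate_thresholds(scores):
        tp, fn, tn, fp = _binary_counts(scores, is_pos, thr, low_is_pos)
        acc, sens = (tp + tn) / len(scores), tp / (tp + fn)
        key = (acc, sens, -thr)
        if best is None or key > best:
            best = key
    return best[0], best[1]


class TestBinaryThreshold:
    def test_perfect_separation(self):
        scores = np.array([90.0, 91, 92, 50, 51, 52])
        stages = np.array(["NC"] * 3 + ["AD"] * 3)
        m = binary_threshold_metrics(scores, stages, ("NC", "AD"))
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)
        assert m.low_score_is_positive

    def test_rates_recomputable_from_confusion(self, rng):
        scores, stages = random_staged_scores(rng, 80, sd=25.0)
        m = binary_threshold_metrics(scores, stages, ("MCI", "AD"))
        c = m.confusion
        assert m.sensitivity == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        assert m.specificity == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))
        assert m.accuracy == pytest.approx(
            (c["tp"] + c["tn"]) / sum(c.values()))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores, stages = random_staged_scores(rng, 150, sd=30.0)
        mask = stages != "MCI"
        scores, stages = scores[mask], stages[mask]
        m = binary_threshold_metrics(scores, stages, ("NC", "AD"))
        acc, sens = brute_force_binary(scores, stages, "AD",
                                       m.low_score_is_positive)
        assert m.accuracy == pytest.approx(acc)
        assert m.sensitivity == pytest.approx(sens)

    def test_definition_arithmetic(self):
        # TP=3 FN=1 TN=4 FP=2 at a fixed threshold
        scores = np.array([1, 2, 3, 9, 1, 2, 8, 8, 8, 8], dtype=float)
        stages = np.array(["AD"] * 4 + ["NC"] * 6)
        is_pos = stages == "AD"
        tp, fn, tn, fp = _binary_counts(scores, is_pos, 3.5, True)
        assert (tp, fn, tn, fp) == (3, 1, 4, 2)
        assert tp / (tp + fn) == pytest.approx(0.75)
        assert tn / (tn + fp) == pytest.approx(2 / 3)
        assert (tp + tn) / 10 == pytest.approx(0.7)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            binary_threshold_metrics([1.0, 2.0], ["NC", "NC"], ("NC", "AD"))

    def test_selection_set_can_differ_from_evaluation_set(self, rng):
        sel_scores, sel_stages = random_staged_scores(rng, 100)
        scores, stages = random_staged_scores(rng, 40)
        m = binary_threshold_metrics(
            scores, stages, ("NC", "AD"),
            selection_scores=sel_scores, selection_stages=sel_stages,
        )
        assert 0.0 <= m.accuracy <= 1.0


def brute_force_threeclass(scores, stages, order):
    """Independent double-loop scan over cut-point pairs."""
    cands = _candidate_thresholds(scores)
    best = None
    for i, c1 in enumerate(cands):
        for c2 in cands[i + 1 :]:
            pred = _predict_threeclass(scores, c1, c2, order)
            acc = float(np.mean(pred == stages))
            if best is None or acc > best:
                best = acc
    return best


class TestThreeClassThreshold:
    def test_perfect_separation(self):
        scores = np.array([90.0, 91, 60, 61, 30, 31])
        stages = np.array(["NC", "NC", "MCI", "MCI", "AD", "AD"])
        m = threeclass_threshold_metrics(scores, stages)
        assert m.overall_accuracy == 1.0
        for st in ("NC", "MCI", "AD"):
            assert m.per_stage[st] == {
                "sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0}
        assert m.stage_order_low_to_high == ("AD", "MCI", "NC")

    def test_per_stage_metrics_consistent_with_confusion(self, rng):
        scores, stages = random_staged_scores(rng, 90, sd=25.0)
        m = threeclass_threshold_metrics(scores, stages)
        n = len(scores)
        for st in ("NC", "MCI", "AD"):
            tp = m.confusion[st][st]
            fn = sum(m.confusion[st].values()) - tp
            fp = sum(m.confusion[t][st] for t in m.confusion) - tp
            tn = n - tp - fn - fp
            assert m.per_stage[st]["sensitivity"] == pytest.approx(
                tp / (tp + fn))
            assert m.per_stage[st]["specificity"] == pytest.approx(
                tn / (tn + fp))
            assert m.per_stage[st]["accuracy"] == pytest.approx((tp + tn) / n)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores, stages = random_staged_scores(rng, 60, sd=30.0)
        m = threeclass_threshold_metrics(scores, stages)
        assert m.overall_accuracy == pytest.approx(
            brute_force_threeclass(scores, stages, m.stage_order_low_to_high)
        )

    def test_missing_stage_rejected(self):
        with pytest.raises(ValueError):
            threeclass_threshold_metrics([1.0, 2.0], ["NC", "AD"])


class TestDispersion:
    def test_quartile_deviation_linear_interpolation(self):
        res = dispersion_table([0.0, 0.5, 1.0])
        assert res.quartile_deviation == pytest.approx((0.75 - 0.25) / 2)

    def test_variation_ratio_mode_arithmetic(self):
        res = dispersion_table([1.0, 1.0, 2.0, 3.0])
        assert res.variation_ratio == pytest.approx(0.5)

    def test_constant_vector_all_zero(self):
        res = dispersion_table([4.2] * 5)
        assert res == type(res)(0.0, 0.0, 0.0, 0.0)

    def test_population_variance_of_normalized_scores(self):
        res = dispersion_table([0.0, 1.0])
        assert res.variance == pytest.approx(0.25)
        assert res.std == pytest.approx(0.5)

    def test_too_few_observations_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            dispersion_table([1.0])


class TestPareto:
    def test_uniform_fill_one_per_bin(self):
        res = pareto_bins(np.arange(10, dtype=float), n_bins=10)
        np.testing.assert_array_equal(res.frequencies, np.ones(10, dtype=int))
        np.testing.assert_allclose(
            res.cumulative_percent, np.arange(10, 101, 10))

    def test_point_mass_jumps_to_100(self):
        res = pareto_bins([5.0] * 7, n_bins=10)
        assert res.frequencies.sum() == 7
        jump = np.argmax(res.frequencies > 0)
        assert res.cumulative_percent[jump] == pytest.approx(100.0)
        assert np.all(res.cumulative_percent[jump:] == 100.0)

    def test_frequencies_conserve_n(self, rng):
        x = rng.normal(size=137)
        res = pareto_bins(x, n_bins=8)
        assert res.frequencies.sum() == 137
        assert res.cumulative_percent[-1] == 100.0
        assert np.all(np.diff(res.cumulative_percent) >= 0)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            pareto_bins([1.0, 2.0], n_bins=1)


class TestFullReport:
    def test_report_invariants_and_serialization(self, rng, tmp_path):
        scores, stages = random_staged_scores(rng, 120, sd=15.0)
        report = evaluate_scores(scores=scores, stages=stages)
        d = report.to_dict()
        assert -1 <= d["correlation"]["pearson"] <= 1
        for pair in d["ttests"].values():
            assert 0 < pair["p"] <= 1
        for task in d["binary"].values():
            for key in ("sensitivity", "specificity", "accuracy"):
                assert 0 <= task[key] <= 1
        assert d["pareto"]["cumulative_percent"][-1] == 100.0
        # byte-identical serialization on re-evaluation
        report2 = evaluate_scores(scores=scores, stages=stages)
        assert report.to_json() == report2.to_json()
        report.save(tmp_path / "report.json")
        report.write_tables(tmp_path / "tables")
        for name in ("correlation", "ttests", "binary_metrics",
                     "threeclass_metrics", "dispersion", "pareto"):
            assert (tmp_path / "tables" / f"{name}.csv").exists()
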