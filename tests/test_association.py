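"""Correlation statistics, the normality gate, and the modeling harness."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emrqi import (
    DefectProfile,
    PerformanceTable,
    association_table,
    default_plan,
    evaluate_models,
    generate_cohort,
    normality_gate,
    one_sided_p,
    pearson,
    spearman,
    study_association_table,
    study_performance,
    study_scores,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -3 * x + 7) == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson(x, y) == pytest.approx(pearson(y, x))
        assert pearson(5 * x + 2, y) == pytest.approx(pearson(x, y))
        assert pearson(-5 * x + 2, y) == pytest.approx(-pearson(x, y))

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y).statistic,
                                              abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestSpearman:
    def test_identical_rankings(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_single_adjacent_swap_n5(self):
        # sum d^2 = 2 -> rho = 1 - 12/120 = 0.9
        assert spearman([1, 2, 3, 4, 5],
                        [1, 3, 2, 4, 5]) == pytest.approx(0.9)

    def test_ties_equal_pearson_on_average_ranks(self):
        x = np.array([1.0, 2, 2, 3, 4, 4, 4])
        y = np.array([2.0, 1, 3, 3, 5, 4, 6])
        rho = spearman(x, y)
        oracle = pearson(stats.rankdata(x), stats.rankdata(y))
        assert rho == pytest.approx(oracle, abs=1e-12)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_equals_pearson_on_ranks_for_all_120_permutations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        for perm in permutations(range(5)):
            y = x[list(perm)]
            assert spearman(x, y) == pytest.approx(
                pearson(x, stats.rankdata(y)), abs=1e-12)

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError):
            spearman([2, 2, 2, 2], [1, 2, 3, 4])


class TestNormalityGate:
    def test_gaussian_pair_chooses_pearson(self):
        rng = np.random.default_rng(10)
        method, _ = normality_gate(rng.normal(size=50), rng.normal(size=50))
        assert method == "pearson"

    def test_skewed_sample_chooses_spearman(self):
        rng = np.random.default_rng(10)
        method, _ = normality_gate(rng.normal(size=50),
                                   rng.exponential(size=50))
        assert method == "spearman"

    def test_decision_flips_exactly_at_min_p(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=40), rng.exponential(size=40) ** 2
        _, (px, py) = normality_gate(x, y)
        threshold = min(px, py)
        for alpha in (threshold / 2, threshold * 2):
            method, _ = normality_gate(x, y, alpha=alpha)
            assert method == ("pearson" if alpha < threshold else "spearman")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1, 2], [1, 2])


class TestOneSidedP:
    def test_zero_coefficient_is_half(self):
        assert one_sided_p(0.0, 10) == pytest.approx(0.5)

    @pytest.mark.parametrize("r, expected", [
        (0.866, 0.029),   # strongly positive at n = 5: significant
        (0.639, 0.123),   # moderate at n = 5: not significant
    ])
    def test_published_n5_pvalues(self, r, expected):
        assert one_sided_p(r, 5) == pytest.approx(expected, abs=1e-3)

    def test_perfect_correlation_zero_by_convention(self):
        assert one_sided_p(1.0, 5) == 0.0

    def test_exact_permutation_p_close_to_t_approx(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.1, 2.3, 2.9, 4.2, 4.8])
        r = pearson(x, y)
        p_exact = one_sided_p(r, 5, exact=True, x=x, y=y)
        assert p_exact == pytest.approx(1 / 120)  # only identity ranking beats it


class TestAssociationTable:
    def test_fixture_reproduction_shape_and_significance(self):
        results = study_association_table()
        assert len(results) == 9
        flags = {f"{r.model}-{r.metric}": r.significant for r in results}
        assert sum(flags.values()) == 8
        assert flags["LR-precision"] is False

    def test_label_mismatch_listed(self):
        scores = pd.Series([0.9, 0.8, 0.7], index=["a", "b", "c"])
        perf = PerformanceTable(values=pd.DataFrame({
            "dataset": ["a", "b", "x"], "model": ["LR"] * 3,
            "accuracy": [0.7, 0.6, 0.5], "precision": [0.7, 0.6, 0.5],
            "auc": [0.7, 0.6, 0.5]}))
        with pytest.raises(ValueError, match="x"):
            association_table(scores, perf)

    def test_identical_performance_undefined(self):
        scores = pd.Series([0.9, 0.8, 0.7], index=["a", "b", "c"])
        perf = PerformanceTable(values=pd.DataFrame({
            "dataset": ["a", "b", "c"], "model": ["LR"] * 3,
            "accuracy": [0.7] * 3, "precision": [0.7] * 3, "auc": [0.7] * 3}))
        results = association_table(scores, perf, gate=False)
        assert all(np.isnan(r.coefficient) for r in results)
        assert not any(r.significant for r in results)
        assert all(r.method == "undefined" for r in results)

    def test_independent_recomputation_of_fixture(self):
        """Each published coefficient equals a second, index-free
        implementation of the product-moment formula."""
        totals = study_scores().set_index("dataset")["total"]
        perf = study_performance()
        for r in study_association_table():
            y = perf.metric_series(r.model, r.metric).loc[totals.index]
            xv, yv = totals.to_numpy(), y.to_numpy()
            n = len(xv)
            num = n * np.sum(xv * yv) - xv.sum() * yv.sum()
            den = np.sqrt((n * np.sum(xv ** 2) - xv.sum() ** 2)
                          * (n * np.sum(yv ** 2) - yv.sum() ** 2))
            assert r.coefficient == pytest.approx(num / den, abs=1e-12)


class TestEvaluateModels:
    def test_null_signal_auc_near_half(self, synth_plan):
        ds, _ = generate_cohort(DefectProfile(
            n_records=1200, outcome_prevalence=0.5, seed=42))
        rng = np.random.default_rng(7)
        ds.records["sepsis"] = rng.integers(0, 2, len(ds.records))
        perf = evaluate_models(ds, synth_plan, seed=7, models=("LR",),
                               cross_validate=False)
        assert perf["auc"].iloc[0] == pytest.approx(0.5, abs=0.1)

    def test_separable_data_perfect_accuracy(self, synth_plan):
        ds, _ = generate_cohort(DefectProfile(
            n_records=800, outcome_prevalence=0.5, seed=5))
        ds.records["sepsis"] = (ds.records["lactate"]
                                > ds.records["lactate"].median()).astype(int)
        perf = evaluate_models(ds, synth_plan, seed=5, models=("RF",),
                               cross_validate=False)
        assert perf["accuracy"].iloc[0] > 0.97

    def test_clean_beats_heavily_defective(self, synth_plan):
        wins = 0
        for seed in range(6):
            clean, _ = generate_cohort(DefectProfile(
                n_records=900, seed=seed))
            dirty, _ = generate_cohort(DefectProfile(
                n_records=900, seed=seed,
                cell_missingness={"inputs": 0.5}, label_noise_rate=0.25))
            a = evaluate_models(clean, synth_plan, seed=seed, models=("LR",),
                                cross_validate=False)["auc"].iloc[0]
            b = evaluate_models(dirty, synth_plan, seed=seed, models=("LR",),
                                cross_validate=False)["auc"].iloc[0]
            wins += a >= b
        assert wins >= 5  # majority direction over paired seeded runs

    def test_single_class_outcome_rejected(self, synth_plan):
        ds, _ = generate_cohort(DefectProfile(n_records=300, seed=1))
        ds.records["sepsis"] = 1
        with pytest.raises(ValueError):
            evaluate_models(ds, synth_plan, seed=1)

    def test_seeded_reproducibility(self, synth_plan):
        ds, _ = generate_cohort(DefectProfile(n_records=600, seed=3))
        a = evaluate_models(ds, synth_plan, seed=9, cross_validate=False)
        b = evaluate_models(ds, synth_plan, seed=9, cross_validate=False)
        pd.testing.assert_frame_equal(a, b)
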