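import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from immunomod.datatypes import SurvivalTable
from immunomod.modules import build_module_set
from immunomod.scoring import median_split, module_score
from immunomod.simulate import SimulationConfig, generate_tumor_cohort
from immunomod.survival import (
    estimate_fdr,
    exact_logrank_p,
    fit_ph_model,
    km_estimate,
    logrank_test,
    permutation_calibration,
    screen_modules,
)
from conftest import make_module, make_survival


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """times (1 event, 2 censored, 3 event): S = 1, 2/3, 2/3, 0."""
        km = km_estimate(make_survival([1, 2, 3], [True, False, True]))
        np.testing.assert_allclose(km.times, [0, 1, 2, 3])
        np.testing.assert_allclose(km.survival, [1, 2 / 3, 2 / 3, 0])
        np.testing.assert_array_equal(km.n_at_risk, [3, 3, 2, 1])
        np.testing.assert_array_equal(km.n_events, [0, 1, 0, 1])
        assert km.median == 3.0

    def test_no_events_survival_stays_one_median_undefined(self):
        km = km_estimate(make_survival([5, 8, 13], [False, False, False]))
        assert (km.survival == 1.0).all()
        assert km.median is None

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(50, size=40).round(2)
        km = km_estimate(make_survival(times, [True] * 40))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(1.0 - (times <= t).mean(), abs=1e-12)

    def test_curve_monotone_within_unit_interval(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(30, 50)
        events = rng.random(50) < 0.6
        km = km_estimate(make_survival(times, events))
        assert km.survival[0] == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival.min() >= 0.0 and km.survival.max() <= 1.0


class TestLogRank:
    def test_identical_groups_give_chi2_zero_p_one(self):
        surv = make_survival([1, 2, 3, 1, 2, 3], [True] * 6)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.sample_ids)
        res = logrank_test(surv, labels)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        surv = make_survival([1, 5, 3, 8, 2, 9], [1, 1, 0, 1, 1, 0])
        labels = pd.Series(["A", "B", "A", "B", "A", "B"], index=surv.sample_ids)
        swapped = labels.map({"A": "B", "B": "A"})
        res_a, res_b = logrank_test(surv, labels), logrank_test(surv, swapped)
        assert res_a.chi_square == pytest.approx(res_b.chi_square)
        assert res_a.p == pytest.approx(res_b.p)

    def test_empty_group_is_error(self):
        surv = make_survival([1, 2, 3, 4], [True] * 4)
        from immunomod.datatypes import Stratification
        strat = Stratification(
            module="m", labels=pd.Series("lo", index=surv.data.index),
            scheme="median_split", group_order=("lo", "hi"))
        with pytest.raises(ValueError, match="zero members"):
            logrank_test(surv, strat)

    def test_matches_lifelines_exactly(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(100, 60)
        events = rng.random(60) < 0.7
        groups = rng.integers(0, 3, 60)
        surv = make_survival(times, events)
        labels = pd.Series([f"g{k}" for k in groups], index=surv.sample_ids)
        res = logrank_test(surv, labels)
        ll = multivariate_logrank_test(times, groups, events)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ll.p_value, rel=1e-9)
        assert res.df == 2

    def test_exhaustive_permutation_oracle_n6(self):
        """Fully separated groups {1,2,3} vs {4,5,6}: the most extreme of the
        20 assignments and its mirror give exact p = 2/20 = 0.1; the
        chi-square approximation (chi2 = 5.0517, p = 0.0246) is a known
        small-sample distance from the enumeration value."""
        surv = make_survival([1, 2, 3, 4, 5, 6], [True] * 6)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.sample_ids)
        res = logrank_test(surv, labels)
        exact = exact_logrank_p(surv, labels)
        assert exact == pytest.approx(0.1)
        assert res.chi_square == pytest.approx(5.051660516605167, rel=1e-12)
        assert abs(res.p - exact) <= 0.08

    def test_chi_square_approaches_exact_p_at_n12(self):
        rng = np.random.default_rng(42)
        times = rng.exponential(100, 12).round(1)
        surv = make_survival(times, [True] * 12)
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=surv.sample_ids)
        assert abs(logrank_test(surv, labels).p - exact_logrank_p(surv, labels)) <= 0.05


class TestScreen:
    def test_survival_linked_module_ranks_first(self, disjoint_config):
        cohort = generate_tumor_cohort(disjoint_config)
        truth_modules = {
            name: make_module(name, genes)
            for name, genes in cohort.truth["module_members"].items()
        }
        from immunomod.datatypes import ModuleSet
        result = screen_modules(cohort.expression, ModuleSet(truth_modules),
                                cohort.survival)
        assert result.table.iloc[0]["module"] == cohort.truth["linked_modules"][0]
        assert result.table.iloc[0]["p"] < 1e-4

    def test_null_screen_p_values_approximately_uniform(self):
        config = SimulationConfig(
            seed=77, beta=0.0, n_tumor_samples=300, n_genes=4200,
            n_modules=200, module_size=20, n_linked_modules=1,
            deletion_locus=("9", "9p21.3", 10))
        cohort = generate_tumor_cohort(config)
        from immunomod.datatypes import ModuleSet
        truth_modules = ModuleSet({
            name: make_module(name, genes)
            for name, genes in cohort.truth["module_members"].items()
        })
        result = screen_modules(cohort.expression, truth_modules, cohort.survival)
        frac = (result.table["p"] < 0.05).mean()
        # 200 nearly independent null tests: binomial 3-sigma band around 5%
        assert 0.005 <= frac <= 0.10

    def test_single_module_gives_one_row(self, tumor_cohort):
        from immunomod.datatypes import ModuleSet
        members = tumor_cohort.truth["module_members"]["MAF.mod"]
        ms = ModuleSet({"MAF.mod": make_module("MAF.mod", members)})
        result = screen_modules(tumor_cohort.expression, ms, tumor_cohort.survival)
        assert len(result.table) == 1

    def test_invariant_to_sample_and_gene_order(self, tumor_cohort):
        from immunomod.datatypes import ExpressionMatrix, ModuleSet
        members = tumor_cohort.truth["module_members"]["IRF7.mod"]
        ms = ModuleSet({"IRF7.mod": make_module("IRF7.mod", members)})
        base = screen_modules(tumor_cohort.expression, ms, tumor_cohort.survival)
        flipped = ExpressionMatrix(tumor_cohort.expression.data.iloc[::-1, ::-1])
        ms_rev = ModuleSet({"IRF7.mod": make_module("IRF7.mod", list(reversed(members)))})
        again = screen_modules(flipped, ms_rev, tumor_cohort.survival)
        assert base.table.iloc[0]["p"] == pytest.approx(again.table.iloc[0]["p"])


class TestPermutationCalibration:
    def test_alpha_one_gives_proportion_one(self, tumor_cohort):
        res = permutation_calibration(tumor_cohort.survival, n_perm=50,
                                      alpha=1.0, seed=1)
        assert res.proportion == 1.0

    def test_same_seed_identical_counts(self, tumor_cohort):
        a = permutation_calibration(tumor_cohort.survival, n_perm=300, alpha=0.05, seed=9)
        b = permutation_calibration(tumor_cohort.survival, n_perm=300, alpha=0.05, seed=9)
        assert a.n_exceed == b.n_exceed

    def test_vectorized_path_matches_scalar_logrank(self, tumor_cohort):
        """One random equal partition evaluated by the scalar test falls at
        the rate the vectorized batch reports."""
        surv = tumor_cohort.survival
        res = permutation_calibration(surv, n_perm=400, alpha=0.5, seed=3)
        rng = np.random.default_rng(3)
        n = len(surv.data)
        hits = 0
        for _ in range(400):
            perm = rng.permutation(n)
            labels = pd.Series(
                ["a"] * (n - n // 2) + ["b"] * (n // 2),
                index=np.asarray(surv.sample_ids)[perm])
            if logrank_test(surv, labels).p < 0.5:
                hits += 1
        # both are draws of the same binomial; they need not share streams
        assert abs(hits / 400 - res.proportion) < 0.12

    def test_null_rate_near_alpha(self):
        config = SimulationConfig(seed=7, beta=0.0, n_genes=300, n_modules=2,
                                  module_size=50, n_linked_modules=1)
        cohort = generate_tumor_cohort(config)
        res = permutation_calibration(cohort.survival, n_perm=4000,
                                      alpha=0.05, seed=21)
        assert res.proportion == pytest.approx(0.05, abs=0.015)


class TestFdr:
    def test_worked_example_one_in_sixteen(self):
        fdr = estimate_fdr(1, 16)
        assert fdr.fraction == pytest.approx(0.0625)
        assert fdr.percent_label == "6%"

    def test_zero_expected_false(self):
        assert estimate_fdr(0, 5).fraction == 0.0

    def test_plain_arithmetic(self):
        assert estimate_fdr(2, 8).fraction == pytest.approx(0.25)

    def test_negative_expected_false_is_error(self):
        with pytest.raises(ValueError):
            estimate_fdr(-1, 4)


class TestCoxModel:
    @staticmethod
    def _cohort(beta, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        times = rng.exponential(1.0 / (1e-3 * np.exp(beta * x)))
        censor = rng.exponential(1 / 4e-4, n)
        frame = pd.DataFrame({
            "time": np.minimum(times, censor),
            "event": times <= censor,
            "x": x,
        }, index=[f"s{i}" for i in range(n)])
        return SurvivalTable(frame)

    def test_null_covariate_estimate_within_two_se(self):
        fit = fit_ph_model(self._cohort(beta=0.0), ["x"])
        row = fit.table.iloc[0]
        assert abs(row["coef"]) < 2 * row["se"]

    def test_recovers_planted_protective_beta(self):
        fit = fit_ph_model(self._cohort(beta=-1.0, seed=3), ["x"])
        row = fit.table.iloc[0]
        assert row["coef"] == pytest.approx(-1.0, abs=2 * row["se"])
        assert fit.wald_p < 1e-10

    def test_hi_group_indicator_sign_opposes_survival_benefit(self, disjoint_config):
        """A median-split 'hi' dummy on a protective score must carry a
        negative log hazard ratio."""
        cohort = generate_tumor_cohort(disjoint_config)
        members = cohort.truth["module_members"]["IRF7.mod"]
        strat = median_split(module_score(cohort.expression,
                                          make_module("IRF7.mod", members)))
        indicator = (strat.labels == "hi").astype(float).rename("isg_hi")
        fit = fit_ph_model(cohort.survival, [indicator])
        assert fit.table.iloc[0]["coef"] < 0

    def test_univariate_mode_stacks_separate_fits(self):
        surv = self._cohort(beta=-0.5, n=400, seed=8)
        rng = np.random.default_rng(1)
        extra = pd.Series(rng.standard_normal(400), index=surv.data.index,
                          name="noise")
        fit = fit_ph_model(surv, ["x", extra], mode="univariate")
        assert list(fit.table["covariate"]) == ["x", "noise"]
        solo = fit_ph_model(surv, ["x"])
        assert fit.table.iloc[0]["coef"] == pytest.approx(
            solo.table.iloc[0]["coef"], rel=1e-8)
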