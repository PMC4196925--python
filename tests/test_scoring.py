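import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from immunomod.datatypes import ExpressionMatrix, Module
from immunomod.modules import build_module_set
from immunomod.scoring import (
    InsufficientGenesError,
    cluster_stratify,
    median_split,
    module_score,
    score_correlation,
)
from conftest import make_module


def _expr(frame):
    return ExpressionMatrix(pd.DataFrame(frame))


class TestModuleScore:
    def test_score_is_median_of_member_genes(self):
        expr = _expr({"s1": [1.0, 5.0, 9.0]})
        expr.data.index = ["g1", "g2", "g3"]
        module = make_module("m.mod", ["g1", "g2", "g3"])
        sv = module_score(expr, module, min_genes=3)
        assert sv.scores["s1"] == 5.0
        assert sv.n_genes_used == 3

    def test_all_members_absent_raises_skip(self):
        expr = _expr({"s1": [1.0], "s2": [2.0]})
        expr.data.index = ["other"]
        module = make_module("m.mod", ["g1", "g2"])
        with pytest.raises(InsufficientGenesError, match="skipped"):
            module_score(expr, module, min_genes=2)

    def test_missing_members_ignored_and_counted(self):
        expr = _expr({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
        expr.data.index = ["g1", "g2"]
        module = make_module("m.mod", ["g1", "g2", "gone"])
        sv = module_score(expr, module, min_genes=2)
        assert (sv.n_genes_used, sv.n_genes_missing) == (2, 1)

    def test_invariant_to_gene_and_sample_order(self, tumor_cohort):
        module = make_module("m.mod", tumor_cohort.truth["module_members"]["IRF7.mod"][:20])
        sv = module_score(tumor_cohort.expression, module)
        flipped = ExpressionMatrix(
            tumor_cohort.expression.data.iloc[::-1, ::-1])
        module_rev = make_module("m.mod", list(reversed(module.genes)))
        sv2 = module_score(flipped, module_rev)
        pd.testing.assert_series_equal(sv.scores.sort_index(), sv2.scores.sort_index())

    def test_tracks_planted_activity(self, tumor_cohort):
        """Score of a planted module follows the latent immune activity."""
        members = tumor_cohort.truth["module_members"]["IRF7.mod"]
        sv = module_score(tumor_cohort.expression, make_module("IRF7.mod", members))
        r = np.corrcoef(sv.scores, tumor_cohort.truth["activity"])[0, 1]
        assert r > 0.9


class TestMedianSplit:
    def test_even_split(self):
        sv = module_score(
            _scores_matrix([1.0, 2.0, 3.0, 4.0]), _unit_module(), min_genes=1)
        strat = median_split(sv)
        assert strat.samples("lo") == ["s0", "s1"]
        assert strat.samples("hi") == ["s2", "s3"]

    def test_odd_n_tie_goes_to_lo(self):
        sv = module_score(
            _scores_matrix([1.0, 2.0, 3.0, 4.0, 5.0]), _unit_module(), min_genes=1)
        strat = median_split(sv)
        assert strat.sizes() == {"lo": 3, "hi": 2}
        assert "s2" in strat.samples("lo")  # the median sample is not "higher"

    def test_cohort_scale_sizes(self):
        rng = np.random.default_rng(0)
        sv = module_score(_scores_matrix(rng.normal(size=291)), _unit_module(),
                          min_genes=1)
        strat = median_split(sv)
        assert strat.sizes() == {"lo": 146, "hi": 145}

    def test_degenerate_identical_scores_error(self):
        sv = module_score(_scores_matrix([2.0] * 6), _unit_module(), min_genes=1)
        with pytest.raises(ValueError, match="degenerate"):
            median_split(sv)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=40, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        from scipy.stats import rankdata

        sv = module_score(_scores_matrix(values), _unit_module(), min_genes=1)
        # ranks are a strictly monotone transform with no float collapse
        transformed = module_score(
            _scores_matrix(list(rankdata(values))), _unit_module(), min_genes=1)
        pd.testing.assert_series_equal(
            median_split(sv).labels, median_split(transformed).labels)


def _scores_matrix(values):
    frame = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(values)},
                         index=["g1"])
    return ExpressionMatrix(frame)


def _unit_module():
    return make_module("m.mod", ["g1"])


class TestClusterStratify:
    def _planted_strata(self, n_per=40, n_genes=30, noise=0.5, seed=0):
        rng = np.random.default_rng(seed)
        activity = np.repeat([-3.0, 0.0, 3.0], n_per)
        values = 5.0 + activity[None, :] + rng.normal(0, noise, (n_genes, 3 * n_per))
        frame = pd.DataFrame(values,
                             index=[f"g{i}" for i in range(n_genes)],
                             columns=[f"s{i}" for i in range(3 * n_per)])
        truth = np.repeat([0, 1, 2], n_per)
        return ExpressionMatrix(frame), make_module("m.mod", list(frame.index)), truth

    def test_k1_single_label(self):
        expr, module, _ = self._planted_strata()
        strat = cluster_stratify(expr, module, k=1)
        assert strat.labels.nunique() == 1

    def test_k_exceeding_samples_is_error(self):
        expr, module, _ = self._planted_strata(n_per=2)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_stratify(expr, module, k=10)

    def test_three_planted_strata_recovered(self):
        expr, module, truth = self._planted_strata()
        strat = cluster_stratify(expr, module, k=3)
        ari = adjusted_rand_score(truth, strat.labels.to_numpy())
        assert ari >= 0.9
        # groups ordered by ascending mean score: lo = planted -3 stratum
        assert set(strat.samples("lo")) == set(strat.labels.index[:40])
        assert set(strat.samples("hi")) == set(strat.labels.index[80:])

    def test_k2_agrees_with_median_split_on_separated_data(self):
        rng = np.random.default_rng(1)
        activity = np.repeat([-2.0, 2.0], 50)
        values = 5.0 + activity[None, :] + rng.normal(0, 0.5, (20, 100))
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(20)],
                             columns=[f"s{i}" for i in range(100)])
        expr = ExpressionMatrix(frame)
        module = make_module("m.mod", list(frame.index))
        k2 = cluster_stratify(expr, module, k=2)
        med = median_split(module_score(expr, module))
        agreement = (k2.labels == med.labels.loc[k2.labels.index]).mean()
        assert agreement >= 0.9

    def test_deterministic(self):
        expr, module, _ = self._planted_strata()
        a = cluster_stratify(expr, module, k=3)
        b = cluster_stratify(expr, module, k=3)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestScoreCorrelation:
    def test_module_with_itself_is_one(self, tumor_cohort):
        members = tumor_cohort.truth["module_members"]["IRF7.mod"]
        module = make_module("IRF7.mod", members)
        r = score_correlation(tumor_cohort.expression, module, module)
        assert r == pytest.approx(1.0)

    def test_shared_factor_modules_strongly_correlated(self, tumor_cohort):
        """IRF7/STAT1 modules share the planted latent factor."""
        mm = tumor_cohort.truth["module_members"]
        r = score_correlation(tumor_cohort.expression,
                              make_module("IRF7.mod", mm["IRF7.mod"]),
                              make_module("STAT1.mod", mm["STAT1.mod"]))
        assert r > 0.8

    def test_independent_factor_modules_uncorrelated(self, tumor_cohort):
        mm = tumor_cohort.truth["module_members"]
        r = score_correlation(tumor_cohort.expression,
                              make_module("MAF.mod", mm["MAF.mod"]),
                              make_module("CD28.mod", mm["CD28.mod"]))
        assert abs(r) < 0.2

    def test_too_few_shared_samples_is_error(self):
        expr = _scores_matrix([1.0, 2.0])
        with pytest.raises(ValueError, match="shared samples"):
            score_correlation(expr, _unit_module(), _unit_module(), min_genes=1)
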