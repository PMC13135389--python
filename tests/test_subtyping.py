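"""RAS subclassification rules and association statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import egfr_msig as em
from egfr_msig.clanc import ClassificationResult
from egfr_msig.containers import CohortAnnotation
from egfr_msig.exceptions import JoinError


def make_annotation(sample_id="S1", **overrides):
    base = dict(
        sample_id=sample_id,
        egfr_mutant=False,
        ras_mutant=True,
        tp53_mutant=False,
        stk11_mutant=False,
        keap1_mutant=False,
        cdkn2a_altered=False,
        subtype="bronchioid",
        platform="A",
        survival_months=24.0,
        event=False,
    )
    base.update(overrides)
    return CohortAnnotation(**base)


def make_call(sample_id="S1", positive=True):
    score = 1.0 if positive else -1.0
    return ClassificationResult(
        sample_id=sample_id,
        msig_score=score,
        msig_call="mSig+" if positive else "mSig-",
        distance_mt=0.0,
        distance_wt=0.0,
    )


class TestAssignRasClass:
    def test_msig_positive_is_k_egfr(self):
        label = em.assign_ras_class(make_annotation(), make_call(positive=True))
        assert label.ras_class == "K_EGFR"
        assert "mSig+" in label.rule_fired

    @pytest.mark.parametrize("lesion", ["stk11_mutant", "keap1_mutant"])
    def test_msig_negative_with_metabolic_lesion_is_k_ox(self, lesion):
        ann = make_annotation(**{lesion: True})
        label = em.assign_ras_class(ann, make_call(positive=False))
        assert label.ras_class == "K_Ox"
        assert "K-Ox" in label.rule_fired

    def test_msig_negative_with_tp53_is_k_tp53(self):
        ann = make_annotation(tp53_mutant=True)
        label = em.assign_ras_class(ann, make_call(positive=False))
        assert label.ras_class == "K_TP53"
        assert "TP53" in label.rule_fired

    def test_non_ras_mutant_passes_through(self):
        ann = make_annotation(ras_mutant=False)
        label = em.assign_ras_class(ann, make_call(positive=True))
        assert label.ras_class == "not_RAS_mutant"

    def test_metabolic_clause_precedes_tp53(self):
        ann = make_annotation(tp53_mutant=True, stk11_mutant=True)
        label = em.assign_ras_class(ann, make_call(positive=False))
        assert label.ras_class == "K_Ox"

    def test_msig_clause_precedes_everything(self):
        ann = make_annotation(tp53_mutant=True, stk11_mutant=True, keap1_mutant=True)
        label = em.assign_ras_class(ann, make_call(positive=True))
        assert label.ras_class == "K_EGFR"

    def test_no_qualifying_comutation_unclassified(self):
        label = em.assign_ras_class(make_annotation(), make_call(positive=False))
        assert label.ras_class == "RAS_unclassified"

    def test_mismatched_sample_ids_rejected(self):
        with pytest.raises(JoinError):
            em.assign_ras_class(make_annotation("S1"), make_call("S2"))


def fisher_p_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    if n == 0:
        return 1.0
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in support}
    observed = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-7)))


class TestFisherOr:
    def test_balanced_table(self):
        result = em.fisher_or([[5, 5], [5, 5]])
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0)
        assert not result.correction_applied

    def test_enumeration_oracle_example(self):
        result = em.fisher_or([[8, 2], [1, 9]])
        assert result.odds_ratio == pytest.approx(36.0)
        assert result.p_value == pytest.approx(fisher_p_oracle(8, 2, 1, 9), abs=1e-12)

    def test_zero_cell_haldane_correction(self):
        result = em.fisher_or([[10, 0], [0, 10]])
        assert result.correction_applied
        assert result.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_matches_enumeration_on_small_margins(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if max(a + b, c + d, a + c, b + d) > 6:
                continue
            result = em.fisher_or([[a, b], [c, d]])
            assert result.p_value == pytest.approx(
                fisher_p_oracle(a, b, c, d), abs=1e-10
            ), (a, b, c, d)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            em.fisher_or([[1, -2], [3, 4]])


class TestChiSquare:
    def test_independent_table_is_zero(self):
        result = em.chi_square_association([[25, 25], [25, 25]])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_direct_summation_oracle(self):
        table = np.array([[30, 10], [10, 30]])
        result = em.chi_square_association(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert result.statistic == pytest.approx(oracle, abs=1e-12)
        assert result.p_value == pytest.approx(
            stats.chi2.sf(oracle, 1), abs=1e-12
        )

    def test_three_by_two_degrees_of_freedom(self):
        result = em.chi_square_association([[10, 5], [8, 7], [3, 12]])
        assert result.dof == 2

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            em.chi_square_association([[0, 0], [5, 5]])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        values = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, _ = em.anova_expression_by_group(values, groups)
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(14)
        values = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)])
        groups = ["a"] * 12 + ["b"] * 15
        f, p_f = em.anova_expression_by_group(values, groups)
        t, p_t = stats.ttest_ind(values[:12], values[12:], equal_var=True)
        assert f == pytest.approx(t**2, abs=1e-9)
        assert p_f == pytest.approx(p_t, abs=1e-9)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(15)
        values = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
        )
        groups = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        _, p = em.anova_expression_by_group(values, groups)
        assert p < 0.001

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            em.anova_expression_by_group([1, 2, 3], ["a", "a", "b"])


class TestSummarizeFramework:
    def _cohort_calls(self, cohort, model):
        matrix = em.apply_recipe(
            cohort.expression, ("median_center_genes", "zscore_genes")
        )
        return em.classify(matrix, model)

    def test_msig_fraction_highest_in_bronchioid(self, training_cohort, trained_model):
        results = self._cohort_calls(training_cohort, trained_model)
        ras = em.assign_ras_classes(training_cohort.annotation, results)
        table = em.summarize_framework(training_cohort.annotation, results, ras)
        fractions = table["msig_pos_fraction"]
        assert fractions.idxmax() == "bronchioid"

    def test_proportions_sum_to_one_per_subtype(self, training_cohort, trained_model):
        results = self._cohort_calls(training_cohort, trained_model)
        ras = em.assign_ras_classes(training_cohort.annotation, results)
        table = em.summarize_framework(training_cohort.annotation, results, ras)
        prop_cols = [c for c in table.columns if str(c).startswith("prop_")]
        np.testing.assert_allclose(table[prop_cols].sum(axis=1), 1.0)

    def test_single_subtype_cohort_single_row(self):
        annotations = [
            make_annotation(f"S{i}", ras_mutant=False, subtype="squamoid")
            for i in range(5)
        ]
        results = [make_call(f"S{i}", positive=False) for i in range(5)]
        ras = em.assign_ras_classes(annotations, results)
        table = em.summarize_framework(annotations, results, ras)
        assert len(table) == 1

    def test_unmatched_samples_listed(self):
        annotations = [make_annotation("S1"), make_annotation("S2")]
        results = [make_call("S1")]
        with pytest.raises(JoinError, match="S2"):
            em.assign_ras_classes(annotations, results)
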