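"""Nearest-centroid mSig core: selection, centroids, classification."""

import dataclasses

import numpy as np
import pytest

import egfr_msig as em
from egfr_msig.exceptions import CoverageError
from egfr_msig.sam import GeneScore

from conftest import DESK_RECIPE, desk_pipeline_config


def scores_from_d(d_by_gene):
    return [
        GeneScore(gene_id=g, d=d, t=d, mean_mt=0.0, mean_wt=0.0, s=1.0)
        for g, d in d_by_gene.items()
    ]


def one_gene_model(c_mt=10.0, c_wt=0.0, scale=1.0):
    return em.SignatureModel(
        up_genes=["g1"],
        down_genes=[],
        centroid_mt={"g1": c_mt},
        centroid_wt={"g1": c_wt},
        pooled_scale={"g1": scale},
    )


class TestSelectSignatureGenes:
    def test_signed_split_example(self):
        scores = scores_from_d({"g1": 3, "g2": 2, "g3": 1, "g4": -1, "g5": -2})
        up, down = em.select_signature_genes(scores, n_up=2, n_down=1)
        assert up == ["g1", "g2"]
        assert down == ["g5"]

    def test_deficit_named_in_error(self):
        scores = scores_from_d({"g1": 3, "g2": -1, "g3": -2})
        with pytest.raises(ValueError, match="deficit 2"):
            em.select_signature_genes(scores, n_up=3, n_down=1)

    def test_planted_signature_recovery(self, training_cohort, normalized_training):
        matrix, labels = normalized_training
        scores = em.sam_d_statistics(matrix, labels)
        up, down = em.select_signature_genes(scores, n_up=101, n_down=49)
        planted = set(training_cohort.planted_genes)
        recovered = len(planted & set(up + down))
        assert recovered / len(planted) >= 0.90


class TestFitCentroids:
    def test_hand_worked_one_gene(self):
        matrix = em.ExpressionMatrix(
            ["g1"], ["a", "b", "c", "d"], [[9, 11, -1, 1]]
        )
        labels = np.array([True, True, False, False])
        model = em.fit_centroids(matrix, labels, ["g1"], [])
        assert model.centroid_mt["g1"] == pytest.approx(10.0)
        assert model.centroid_wt["g1"] == pytest.approx(0.0)
        assert model.pooled_scale["g1"] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        matrix = em.ExpressionMatrix(["g1"], ["a", "b"], [[1, 2]])
        with pytest.raises(ValueError, match="both classes"):
            em.fit_centroids(matrix, np.array([True, True]), ["g1"], [])

    def test_refit_is_deterministic(self, normalized_training, trained_model):
        matrix, labels = normalized_training
        refit = em.fit_centroids(
            matrix, labels, trained_model.up_genes, trained_model.down_genes
        )
        assert refit.up_genes == trained_model.up_genes
        assert refit.centroid_mt == trained_model.centroid_mt
        assert refit.pooled_scale == trained_model.pooled_scale

    def test_missing_selected_gene_listed(self, normalized_training):
        matrix, labels = normalized_training
        with pytest.raises(KeyError, match="ghost"):
            em.fit_centroids(matrix, labels, ["ghost"], [])

    def test_direction_violating_gene_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(2, 8))
        values[0, :4] += 2.0  # g0 genuinely up
        values[1, :4] -= 2.0  # g1 down, but requested as up
        matrix = em.ExpressionMatrix(
            ["g0", "g1"], [f"s{i}" for i in range(8)], values
        )
        labels = np.array([True] * 4 + [False] * 4)
        with pytest.warns(UserWarning, match="directionality"):
            model = em.fit_centroids(matrix, labels, ["g0", "g1"], [])
        assert model.up_genes == ["g0"]
        assert model.training_meta["n_dropped_direction"] == 1


class TestClassify:
    def test_sample_on_mutant_centroid(self):
        model = one_gene_model()
        matrix = em.ExpressionMatrix(["g1"], ["x"], [[10.0]])
        result = em.classify(matrix, model)[0]
        assert result.distance_mt == pytest.approx(0.0)
        assert result.msig_call == "mSig+"

    def test_equidistant_tie_goes_negative(self):
        model = one_gene_model()
        matrix = em.ExpressionMatrix(["g1"], ["x"], [[5.0]])
        result = em.classify(matrix, model)[0]
        assert result.msig_score == pytest.approx(0.0, abs=1e-12)
        assert result.msig_call == "mSig-"

    def test_hand_worked_score(self):
        model = one_gene_model()
        matrix = em.ExpressionMatrix(["g1"], ["x"], [[2.0]])
        result = em.classify(matrix, model)[0]
        assert result.msig_score == pytest.approx(4 - 64)
        assert result.msig_call == "mSig-"

    def test_affine_transform_invariance(self, trained_model, validation_cohort):
        matrix = em.apply_recipe(validation_cohort.expression, DESK_RECIPE)
        base = em.classify(matrix, trained_model)
        rng = np.random.default_rng(17)
        genes = trained_model.genes
        a = rng.uniform(0.5, 2.0, size=len(genes))
        b = rng.normal(0, 3, size=len(genes))
        sub = matrix.subset_genes(genes)
        transformed = em.ExpressionMatrix(
            genes, sub.sample_ids, sub.values * a[:, None] + b[:, None]
        )
        warped = em.SignatureModel(
            up_genes=list(trained_model.up_genes),
            down_genes=list(trained_model.down_genes),
            centroid_mt={g: a[i] * trained_model.centroid_mt[g] + b[i]
                         for i, g in enumerate(genes)},
            centroid_wt={g: a[i] * trained_model.centroid_wt[g] + b[i]
                         for i, g in enumerate(genes)},
            pooled_scale={g: a[i] * trained_model.pooled_scale[g]
                          for i, g in enumerate(genes)},
        )
        out = em.classify(transformed, warped)
        for r_base, r_out in zip(base, out):
            assert r_out.msig_score == pytest.approx(r_base.msig_score, rel=1e-9)
            assert r_out.msig_call == r_base.msig_call

    def test_score_antisymmetry_under_class_swap(self, trained_model, validation_cohort):
        matrix = em.apply_recipe(validation_cohort.expression, DESK_RECIPE)
        swapped = em.SignatureModel(
            up_genes=list(trained_model.down_genes),
            down_genes=list(trained_model.up_genes),
            centroid_mt=dict(trained_model.centroid_wt),
            centroid_wt=dict(trained_model.centroid_mt),
            pooled_scale=dict(trained_model.pooled_scale),
        )
        base = em.classify(matrix, trained_model)
        flipped = em.classify(matrix, swapped)
        for r_base, r_flip in zip(base, flipped):
            assert r_flip.msig_score == pytest.approx(-r_base.msig_score, rel=1e-9)

    def test_training_accuracy_on_separable_data(self):
        rng = np.random.default_rng(21)
        values = rng.normal(0, 0.05, size=(20, 30))
        values[:10, :10] += 5.0
        matrix = em.ExpressionMatrix(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(30)], values
        )
        labels = np.array([True] * 10 + [False] * 20)
        model = em.fit_centroids(
            matrix, labels, [f"g{i}" for i in range(10)], []
        )
        calls = [r.msig_call == "mSig+" for r in em.classify(matrix, model)]
        assert (np.array(calls) == labels).all()

    def test_coverage_floor_enforced(self, trained_model):
        genes = trained_model.genes[:10]  # far below the 50% floor
        rng = np.random.default_rng(2)
        matrix = em.ExpressionMatrix(
            genes, ["s0"], rng.normal(size=(len(genes), 1))
        )
        with pytest.raises(CoverageError, match="%"):
            em.classify(matrix, trained_model)


class TestHarmonizeGeneSpace:
    def test_identity_on_matching_space(self, trained_model, normalized_training):
        matrix, _ = normalized_training
        harmonized, missing = em.harmonize_gene_space(matrix, trained_model)
        assert missing == []
        assert harmonized.gene_ids == trained_model.genes

    def test_disjoint_space_rejected(self, trained_model):
        matrix = em.ExpressionMatrix(["zz1", "zz2"], ["s0"], [[1.0], [2.0]])
        with pytest.raises(CoverageError, match="no model genes"):
            em.harmonize_gene_space(matrix, trained_model)

    def test_random_gene_dropout_changes_few_calls(
        self, trained_model, validation_cohort
    ):
        matrix = em.apply_recipe(validation_cohort.expression, DESK_RECIPE)
        base_calls = [r.msig_call for r in em.classify(matrix, trained_model)]
        rng = np.random.default_rng(31)
        keep = [g for g in matrix.gene_ids if rng.random() > 0.10]
        dropped = matrix.subset_genes(keep)
        harmonized, missing = em.harmonize_gene_space(dropped, trained_model)
        assert missing  # some signature genes really were dropped
        new_calls = [r.msig_call for r in em.classify(harmonized, trained_model)]
        changed = sum(a != b for a, b in zip(base_calls, new_calls))
        assert changed / len(base_calls) < 0.02
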