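import dataclasses

import numpy as np
import pytest

import egfr_msig as em

DESK_RECIPE = ("median_center_genes", "zscore_genes")


def desk_pipeline_config(seed: int = 7) -> em.PipelineConfig:
    """Pipeline settings matched to the desk-scale synthetic signature:
    150 planted genes split in the 690:330 up/down proportion."""
    return em.PipelineConfig(n_signature_genes=150, n_up=101, n_down=49, seed=seed)


@pytest.fixture(scope="session")
def default_sim() -> em.SimulationConfig:
    return em.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def training_cohort(default_sim):
    return em.simulate_cohort(default_sim)


@pytest.fixture(scope="session")
def normalized_training(training_cohort):
    matrix = em.apply_recipe(training_cohort.expression, DESK_RECIPE)
    labels = np.array([a.egfr_mutant for a in training_cohort.annotation])
    return matrix, labels


@pytest.fixture(scope="session")
def trained_model(normalized_training):
    matrix, labels = normalized_training
    model = em.train_signature(matrix, labels, desk_pipeline_config())
    model.training_meta["recipe"] = list(DESK_RECIPE)
    return model


@pytest.fixture(scope="session")
def validation_cohort(default_sim):
    return em.simulate_cohort(dataclasses.replace(default_sim, seed=1007))


def small_matrix(seed: int = 0, n_genes: int = 50, n_samples: int = 20):
    rng = np.random.default_rng(seed)
    return em.ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        rng.normal(size=(n_genes, n_samples)),
    )
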