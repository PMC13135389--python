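"""Synthetic LUAD-like cohort generator.

Generates expression matrices and annotations with the structure the mSig
analysis assumes: three expression subtypes with coupled lineage-marker
blocks, EGFR-mutant samples carrying a planted multi-gene signature, a
RAS-mutant subgroup sharing the identical signature (the K-EGFR-like
carriers), signature-negative EGFR mutants confined to the magnoid stratum,
subtype-dependent comutation frequencies, an optional platform batch shift,
and exponential survival whose hazard is raised for signature non-carriers.

The generator is the study-condition oracle for every downstream stage:
truth flags and the planted gene lists ride along for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import SimulationConfig
from .containers import CohortAnnotation, ExpressionMatrix
from .exceptions import ConfigError

_SUBTYPE_NAMES = ("bronchioid", "magnoid", "squamoid")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth used to build it."""

    expression: ExpressionMatrix
    annotation: list[CohortAnnotation]
    truth: dict[str, bool]  # sample_id -> latent signature-carrier flag
    planted_up: list[str]
    planted_down: list[str]

    @property
    def planted_genes(self) -> list[str]:
        return self.planted_up + self.planted_down


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort under ``config``; deterministic given ``config.seed``."""
    if config.n_signature_genes > config.n_genes:
        raise ConfigError("n_signature_genes exceeds n_genes")
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # mutation status first, subtype conditional on it: EGFR mutants and
    # K-EGFR-like RAS carriers concentrate in the bronchioid stratum
    egfr_mt = rng.random(n) < config.prevalence_egfr_mt
    ras_mt = (~egfr_mt) & (rng.random(n) < config.prevalence_ras_mt)
    ras_carrier = ras_mt & (rng.random(n) < config.frac_ras_with_signature)

    subtype_idx = np.empty(n, dtype=int)
    skewed = egfr_mt | ras_carrier
    subtype_idx[skewed] = rng.choice(
        3, size=int(skewed.sum()), p=config.mutant_subtype_proportions
    )
    subtype_idx[~skewed] = rng.choice(
        3, size=int((~skewed).sum()), p=config.subtype_proportions
    )
    subtypes = np.array(_SUBTYPE_NAMES)[subtype_idx]

    # carriers: every EGFR mutant except a magnoid false-negative fraction,
    # plus the K-EGFR-like RAS subgroup
    carrier = egfr_mt.copy()
    magnoid_mt = egfr_mt & (subtypes == "magnoid")
    carrier[magnoid_mt] = rng.random(int(magnoid_mt.sum())) >= config.fn_rate_magnoid
    carrier |= ras_carrier

    # comutations conditional on subtype
    comut = {gene: np.zeros(n, dtype=bool) for gene in ("tp53", "stk11", "keap1", "cdkn2a")}
    for s_idx, name in enumerate(_SUBTYPE_NAMES):
        mask = subtype_idx == s_idx
        probs = config.comutation_table.get(name, {})
        for gene in comut:
            comut[gene][mask] = rng.random(int(mask.sum())) < probs.get(gene, 0.0)

    # expression: subtype lineage blocks + planted signature + N(0,1) noise
    values = rng.standard_normal((g, n))
    n_marker = min(config.n_lineage_markers, g // 10)
    for s_idx in range(3):
        block = slice(s_idx * n_marker, (s_idx + 1) * n_marker)
        values[block, :][:, subtype_idx == s_idx] += config.lineage_effect

    n_sig = config.n_signature_genes
    n_up = int(round(n_sig * config.frac_up_signature))
    n_down = n_sig - n_up
    # planted genes live outside the lineage-marker blocks
    first_free = 3 * n_marker
    if first_free + n_sig > g:
        raise ConfigError(
            f"need {first_free + n_sig} genes for markers + signature, have {g}"
        )
    up_rows = np.arange(first_free, first_free + n_up)
    down_rows = np.arange(first_free + n_up, first_free + n_sig)
    values[np.ix_(up_rows, np.where(carrier)[0])] += config.effect_size
    values[np.ix_(down_rows, np.where(carrier)[0])] -= config.effect_size

    # exponential survival; non-carriers bear the hazard-ratio penalty;
    # uniform censoring on (0, horizon]
    hazard = np.where(
        carrier,
        config.baseline_hazard_per_month,
        config.baseline_hazard_per_month * config.hazard_ratio_msig,
    )
    death = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0.0, config.censoring_horizon_months, size=n)
    time = np.minimum(death, censor)
    event = death <= censor

    annotation = [
        CohortAnnotation(
            sample_id=sample_ids[i],
            egfr_mutant=bool(egfr_mt[i]),
            ras_mutant=bool(ras_mt[i]),
            tp53_mutant=bool(comut["tp53"][i]),
            stk11_mutant=bool(comut["stk11"][i]),
            keap1_mutant=bool(comut["keap1"][i]),
            cdkn2a_altered=bool(comut["cdkn2a"][i]),
            subtype=str(subtypes[i]),
            platform=config.platform,
            survival_months=float(time[i]),
            event=bool(event[i]),
        )
        for i in range(n)
    ]
    return SyntheticCohort(
        expression=ExpressionMatrix(gene_ids, sample_ids, values),
        annotation=annotation,
        truth={sample_ids[i]: bool(carrier[i]) for i in range(n)},
        planted_up=[gene_ids[i] for i in up_rows],
        planted_down=[gene_ids[i] for i in down_rows],
    )


def apply_platform_shift(
    cohort: SyntheticCohort,
    shift_sd: float,
    seed: int,
    platform: str = "platformB",
) -> SyntheticCohort:
    """Re-express the cohort as if assayed on a second platform.

    Every gene receives a random additive offset (SD ``shift_sd``) and a
    positive multiplicative scale jitter, shared by all samples; platform
    labels are updated.  ``shift_sd = 0`` leaves expression untouched.
    """
    if shift_sd < 0:
        raise ConfigError("shift_sd must be >= 0")
    expr = cohort.expression
    if shift_sd == 0:
        values = expr.values.copy()
    else:
        rng = np.random.default_rng(seed)
        offsets = rng.normal(0.0, shift_sd, size=expr.n_genes)
        scales = np.exp(rng.normal(0.0, shift_sd / 2.0, size=expr.n_genes))
        values = expr.values * scales[:, None] + offsets[:, None]
    annotation = [replace(a, platform=platform) for a in cohort.annotation]
    return SyntheticCohort(
        expression=ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values),
        annotation=annotation,
        truth=dict(cohort.truth),
        planted_up=list(cohort.planted_up),
        planted_down=list(cohort.planted_down),
    )
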