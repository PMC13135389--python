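"""Pipeline and simulation configuration objects.

Defaults encode the study conditions the pipeline is designed around: a
1,020-gene signature split 690 up / 330 down, 10-fold cross-validation, and
a 36-month administrative survival horizon.  The simulation defaults encode
a desk-scale training cohort (200 samples, 1,000 genes, 150 planted
signature genes at 2 SD, 15% EGFR-mutant prevalence) with the qualitative
cohort structure the analysis assumes: bronchioid-enriched mutants, a
RAS-mutant subgroup sharing the signature, magnoid false negatives, and
subtype-dependent comutation frequencies (e.g. TP53 in >90% of squamoid
tumors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .exceptions import ConfigError

S0_POLICIES = ("fixed", "median_s", "tusher_percentile_scan")


@dataclass
class PipelineConfig:
    """Settings for signature training, evaluation, and survival stages."""

    n_signature_genes: int = 1020
    n_up: int = 690
    n_down: int = 330
    cv_folds: int = 10
    s0_policy: str = "median_s"
    s0_fixed: float = 0.0
    seed: int = 0
    censor_horizon_months: float = 36.0
    recipe: tuple[str, ...] = ("median_center_genes", "zscore_genes")

    def __post_init__(self) -> None:
        if self.n_up <= 0 or self.n_down <= 0 or self.n_signature_genes <= 0:
            raise ConfigError("gene counts must be positive")
        if self.n_up + self.n_down != self.n_signature_genes:
            raise ConfigError(
                f"n_up + n_down = {self.n_up + self.n_down} must equal "
                f"n_signature_genes = {self.n_signature_genes}"
            )
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.s0_policy not in S0_POLICIES:
            raise ConfigError(f"s0_policy must be one of {S0_POLICIES}")


#: Per-subtype comutation probabilities (TP53, STK11, KEAP1, CDKN2A).
#: Squamoid TP53 exceeds 0.9; magnoid is enriched for STK11/KEAP1 (19p).
DEFAULT_COMUTATION_TABLE: dict[str, dict[str, float]] = {
    "bronchioid": {"tp53": 0.25, "stk11": 0.05, "keap1": 0.05, "cdkn2a": 0.15},
    "magnoid": {"tp53": 0.45, "stk11": 0.55, "keap1": 0.45, "cdkn2a": 0.30},
    "squamoid": {"tp53": 0.92, "stk11": 0.10, "keap1": 0.10, "cdkn2a": 0.35},
}


@dataclass
class SimulationConfig:
    """Synthetic-cohort generator settings.

    ``frac_ras_with_signature`` is the planted K-EGFR-like rate: the
    fraction of RAS-mutant, EGFR-wild-type samples that carry the identical
    planted signature.  ``fn_rate_magnoid`` is the fraction of EGFR-mutant
    magnoid samples that are signature non-carriers (planted false
    negatives).  ``hazard_ratio_msig`` multiplies the exponential death
    hazard of signature NON-carriers (carriers have the favorable outcome).
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_signature_genes: int = 150
    frac_up_signature: float = 690 / 1020
    effect_size: float = 2.0
    subtype_proportions: tuple[float, float, float] = (0.45, 0.25, 0.30)
    prevalence_egfr_mt: float = 0.15
    prevalence_ras_mt: float = 0.30
    frac_ras_with_signature: float = 0.40
    fn_rate_magnoid: float = 0.80
    comutation_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMUTATION_TABLE.items()}
    )
    mutant_subtype_proportions: tuple[float, float, float] = (0.75, 0.10, 0.15)
    n_lineage_markers: int = 30
    lineage_effect: float = 1.5
    platform: str = "platformA"
    platform_shift_sd: float = 0.0
    baseline_hazard_per_month: float = 0.012
    hazard_ratio_msig: float = 2.5
    censoring_horizon_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_up_signature": self.frac_up_signature,
            "prevalence_egfr_mt": self.prevalence_egfr_mt,
            "prevalence_ras_mt": self.prevalence_ras_mt,
            "frac_ras_with_signature": self.frac_ras_with_signature,
            "fn_rate_magnoid": self.fn_rate_magnoid,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        for props, name in (
            (self.subtype_proportions, "subtype_proportions"),
            (self.mutant_subtype_proportions, "mutant_subtype_proportions"),
        ):
            if len(props) != 3 or any(p < 0 for p in props):
                raise ConfigError(f"{name} must be 3 non-negative fractions")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 within 1e-9")
        if self.n_signature_genes > self.n_genes:
            raise ConfigError(
                f"n_signature_genes ({self.n_signature_genes}) exceeds "
                f"n_genes ({self.n_genes})"
            )
        if self.platform_shift_sd < 0:
            raise ConfigError("platform_shift_sd must be >= 0")
        if self.hazard_ratio_msig <= 0:
            raise ConfigError("hazard_ratio_msig must be positive")
        for subtype, probs in self.comutation_table.items():
            for gene, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"comutation_table[{subtype}][{gene}] = {p} not in [0, 1]"
                    )


def load_config(path: str) -> tuple[PipelineConfig, SimulationConfig]:
    """Read a YAML document with optional ``pipeline:`` and ``simulation:`` blocks."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    pipe_raw = dict(raw.get("pipeline") or {})
    if "recipe" in pipe_raw:
        pipe_raw["recipe"] = tuple(pipe_raw["recipe"])
    pipeline = PipelineConfig(**pipe_raw)
    sim_raw = dict(raw.get("simulation") or {})
    for key in ("subtype_proportions", "mutant_subtype_proportions"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    simulation = SimulationConfig(**sim_raw)
    return pipeline, simulation


def dump_config(pipeline: PipelineConfig, simulation: SimulationConfig, path: str) -> None:
    doc = {"pipeline": asdict(pipeline), "simulation": asdict(simulation)}
    doc["pipeline"]["recipe"] = list(pipeline.recipe)
    doc["simulation"]["subtype_proportions"] = list(simulation.subtype_proportions)
    doc["simulation"]["mutant_subtype_proportions"] = list(
        simulation.mutant_subtype_proportions
    )
    doc["simulation"]["comutation_table"] = {
        k: dict(v) for k, v in simulation.comutation_table.items()
    }
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)
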