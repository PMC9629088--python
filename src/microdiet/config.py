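"""Run configuration and the deterministic seed-expansion scheme.

A single top-level ``seed`` drives every stage. Each stage draws its own
independent stream via :func:`stage_seed`, which hashes the stage name into a
``numpy.random.SeedSequence`` alongside the master seed — so adding or
reordering stages never shifts another stage's stream.
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

# kept in sync with the generator's default dysbiosis signature
from .synth import DEFAULT_EFFECT_TAXA as _DEFAULT_EFFECT_TAXA

#: Default master seed used when a config file leaves ``seed`` unset.
DEFAULT_SEED = 17


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the master seed and a stage name."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), tag]).generate_state(1)[0] % (2**31))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Section):
    """Synthetic cohort layout mirroring the pilot study: 34 healthy controls
    and 25 IBS-M patients, of whom 14 receive the personalized diet and 11 the
    standard diet."""

    n_healthy: int = Field(34, ge=2)
    n_ibs: int = Field(25, ge=2)
    n_taxa: int = Field(50, ge=2)
    n_personalized: int = Field(14, ge=1)
    n_control: int = Field(11, ge=1)
    # log2 fold-changes (IBS vs healthy): a dysbiosis signature led by
    # Faecalibacterium depletion and Ruminococcus enrichment
    effect_taxa: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_EFFECT_TAXA)
    )
    log_sd: float = Field(0.6, gt=0)
    zero_inflation: float = Field(0.3, ge=0, le=1)


class CVConfig(_Section):
    cv_folds: int = Field(5, ge=2)
    n_seeds: int = Field(10, ge=1)
    n_tuning_trials: int = Field(0, ge=0)  # 0 = skip tuning, use default config


class MetropolisConfig(_Section):
    p_perturb: float = Field(0.1, gt=0, le=1)
    kernel_sd: float = Field(0.25, gt=0)
    temperature: float = Field(0.02, gt=0)
    n_iterations: int = Field(2000, ge=0)
    distance_budget: Optional[float] = Field(2.0, gt=0)


class StatsConfig(_Section):
    alpha: float = Field(0.05, gt=0, lt=1)
    n_permutations: int = Field(9999, ge=1)


class ClinicalConfig(_Section):
    """Linear coupling of simulated symptom totals to the microbiome index."""

    slope: float = 300.0
    intercept: float = 150.0
    noise_sd: float = Field(40.0, ge=0)


class RunConfig(_Section):
    seed: int = DEFAULT_SEED
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    cv: CVConfig = Field(default_factory=CVConfig)
    metropolis: MetropolisConfig = Field(default_factory=MetropolisConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    clinical: ClinicalConfig = Field(default_factory=ClinicalConfig)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; absent keys fall back to defaults.

    Unknown keys and type mismatches raise ``ValueError`` naming the key.
    ``path=None`` (or an empty file) yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(open(path).read())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        data = loaded
    if overrides:
        data.update(overrides)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors())
        raise ValueError(f"invalid configuration ({locs})") from exc
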