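"""Synthetic cohorts, taxonomies, interventions, and clinical scores.

No public microbiome data accompany the study this pipeline replicates, so
every downstream stage is exercised on generated data with the statistical
structure the analysis assumes:

* **Cohorts** — logistic-normal compositions: independent per-taxon Gaussians
  on the log scale, exponentiated and closed to the simplex. Disease effects
  are injected as log2 fold-changes on named taxa (e.g. Faecalibacterium
  depleted and Ruminococcus enriched in the IBS group) before closure, which
  is exactly the directional-shift language in which genus-level differences
  are reported. This is a stand-in distribution: real gut profiles have
  taxon-taxon correlation structure the independent-log-normal model lacks.
* **Trees** — random rooted binary taxonomies over the simulated genera,
  needed only to give unweighted UniFrac a branch-length structure.
* **Interventions** — a declared linear nutrient-response model acting in clr
  space, so recovered nutrient recommendations can be validated against the
  generating truth.
* **Clinical scores** — five-item symptom-severity records whose totals are
  linearly coupled to the microbiome index with Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .compositions import closure, clr, clr_inverse, ensure_positive
from .io import CLINICAL_ITEMS, AbundanceTable

# Genera highlighted by the cohort comparison, padded with realistic gut genera.
_GENUS_POOL = [
    "Faecalibacterium", "Ruminococcus", "Bacteroides", "Prevotella",
    "Propionibacterium", "Bifidobacterium", "Clostridium", "Blautia",
    "Roseburia", "Akkermansia", "Alistipes", "Dialister", "Dorea",
    "Coprococcus", "Eubacterium", "Lactobacillus", "Streptococcus",
    "Oscillospira", "Parabacteroides", "Phascolarctobacterium",
    "Sutterella", "Veillonella", "Collinsella", "Desulfovibrio",
    "Odoribacter", "Paraprevotella", "Butyricimonas", "Anaerostipes",
    "Megasphaera", "Haemophilus",
]

#: Default log2 fold-changes (IBS vs healthy): a dysbiosis signature led by
#: Faecalibacterium depletion and Ruminococcus enrichment.
DEFAULT_EFFECT_TAXA = {
    "Faecalibacterium": -1.5, "Ruminococcus": 1.5, "Clostridium": -1.0,
    "Bacteroides": 1.0, "Bifidobacterium": -1.0, "Roseburia": -0.75,
    "Prevotella": 0.75, "Streptococcus": 1.0, "Akkermansia": -0.75,
    "Blautia": 0.5,
}

#: Fixed allocation weights of the symptom total across the five items
#: (pain, pain frequency, distension, bowel dissatisfaction, QoL interference),
#: chosen to match typical pre-intervention item proportions.
SSS_ITEM_WEIGHTS = (0.21, 0.17, 0.21, 0.21, 0.20)


def default_taxon_names(n_taxa: int) -> list[str]:
    names = list(_GENUS_POOL[:n_taxa])
    names += [f"Genus{i:03d}" for i in range(len(names), n_taxa)]
    return names


@dataclass
class CohortSpec:
    """Layout of a two-group synthetic cohort on the log-abundance scale."""

    n_healthy: int
    n_ibs: int
    taxon_names: list[str]
    effect_taxa: dict[str, float] = field(default_factory=dict)  # log2 FC, IBS vs healthy
    base_log_mean: np.ndarray | None = None  # natural-log scale, per taxon
    log_sd: np.ndarray | float = 1.0
    zero_inflation: float = 0.0
    seed: int = 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    def validate(self) -> None:
        if self.n_healthy < 2 or self.n_ibs < 2:
            raise ValueError("n_healthy and n_ibs must each be >= 2")
        if self.n_taxa < 2:
            raise ValueError("taxon_names must contain at least 2 taxa")
        if len(set(self.taxon_names)) != self.n_taxa:
            raise ValueError("taxon_names contains duplicates")
        extra = set(self.effect_taxa) - set(self.taxon_names)
        if extra:
            raise ValueError(f"effect_taxa not in taxon_names: {sorted(extra)}")
        if np.any(np.asarray(self.log_sd, dtype=float) <= 0):
            raise ValueError("log_sd must be positive")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.base_log_mean is not None and len(self.base_log_mean) != self.n_taxa:
            raise ValueError("base_log_mean length must equal number of taxa")


def default_cohort_spec(
    n_healthy: int,
    n_ibs: int,
    n_taxa: int = 50,
    effect_taxa: dict[str, float] | None = None,
    log_sd: float = 0.6,
    zero_inflation: float = 0.3,
    seed: int = 0,
) -> CohortSpec:
    """A ready-to-use spec with seed-fixed baseline log-means ~ N(0, 1.5)."""
    names = default_taxon_names(n_taxa)
    base = np.random.default_rng(np.random.SeedSequence([seed, 911])).normal(0.0, 1.5, n_taxa)
    if effect_taxa is None:
        effect_taxa = dict(DEFAULT_EFFECT_TAXA)
    effect_taxa = {t: f for t, f in effect_taxa.items() if t in names}
    return CohortSpec(
        n_healthy=n_healthy,
        n_ibs=n_ibs,
        taxon_names=names,
        effect_taxa=effect_taxa,
        base_log_mean=base,
        log_sd=log_sd,
        zero_inflation=zero_inflation,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, pd.Series]:
    """Draw a healthy + IBS cohort; returns the closed table and group labels.

    IBS rows have each effect taxon's log-mean shifted by ``log2FC * ln 2``
    before closure, so injected effects are exact on the unclosed scale.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_healthy + spec.n_ibs
    base = (
        np.zeros(spec.n_taxa) if spec.base_log_mean is None
        else np.asarray(spec.base_log_mean, dtype=float)
    )
    sd = np.broadcast_to(np.asarray(spec.log_sd, dtype=float), (spec.n_taxa,))

    mean = np.tile(base, (n, 1))
    ibs_rows = np.arange(spec.n_healthy, n)
    for taxon, l2fc in spec.effect_taxa.items():
        j = spec.taxon_names.index(taxon)
        mean[ibs_rows, j] += l2fc * np.log(2.0)

    raw = np.exp(rng.normal(mean, sd))
    if spec.zero_inflation > 0:
        # detection-limit dropout: the lowest `zero_inflation` fraction of each
        # sample's raw abundances falls below the limit and reads as zero, so
        # rare taxa go unobserved more often — the mechanism by which depleted
        # taxa also become absent, as in real presence/absence profiles
        limit = np.quantile(raw, spec.zero_inflation, axis=1, keepdims=True)
        raw = np.where(raw <= limit, 0.0, raw)

    ids = [f"H{i + 1:03d}" for i in range(spec.n_healthy)]
    ids += [f"I{i + 1:03d}" for i in range(spec.n_ibs)]
    table = AbundanceTable(pd.DataFrame(closure(raw), index=ids, columns=spec.taxon_names))
    labels = pd.Series(
        ["healthy"] * spec.n_healthy + ["ibs"] * spec.n_ibs, index=ids, name="group"
    )
    return table, labels


def generate_tree(taxon_names, seed: int = 0) -> TreeNode:
    """Random rooted binary tree with the given leaf set and positive branch lengths."""
    taxon_names = list(taxon_names)
    if len(taxon_names) < 2:
        raise ValueError("a tree needs at least 2 taxa")
    if len(set(taxon_names)) != len(taxon_names):
        raise ValueError("duplicate taxon names")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in taxon_names:
        tip = TreeNode(name=name)
        tip.length = float(rng.uniform(0.1, 1.0))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_clinical(
    index_scores: pd.Series,
    slope: float = 300.0,
    intercept: float = 150.0,
    noise_sd: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-item symptom records linearly coupled to the microbiome index.

    ``total = clip(intercept + slope * index + N(0, noise_sd), 0, 500)``,
    allocated across items by :data:`SSS_ITEM_WEIGHTS` and item-clipped to
    [0, 100]. Noise is added before clipping so totals stay in-range.
    """
    if not np.isfinite(slope) or not np.isfinite(intercept):
        raise ValueError("slope and intercept must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    index_scores = pd.Series(index_scores)
    rng = np.random.default_rng(seed)
    total = intercept + slope * index_scores.to_numpy(dtype=float)
    total = np.clip(total + rng.normal(0.0, noise_sd, len(total)) if noise_sd > 0 else total, 0.0, 500.0)
    items = np.clip(np.outer(total, SSS_ITEM_WEIGHTS), 0.0, 100.0)
    return pd.DataFrame(items, index=index_scores.index, columns=list(CLINICAL_ITEMS))


@dataclass
class InterventionScenario:
    """A baseline cohort plus per-sample nutrient doses driven through a
    known response model — the in-silico analogue of the six-week diet."""

    baseline: AbundanceTable
    nutrient_doses: dict[str, dict[str, float]]  # sample -> nutrient -> g/day
    response: "NutrientResponseModel"  # noqa: F821 - see microdiet.diet
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        missing = set(self.nutrient_doses) - set(self.baseline.sample_ids)
        if missing:
            raise ValueError(f"dosed samples absent from baseline: {sorted(missing)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_intervention(scenario: InterventionScenario) -> AbundanceTable:
    """Apply the nutrient-response model: post = clr⁻¹(clr(pre) + B·η + noise).

    Samples without doses receive η = 0 (noise only). Unknown nutrient names
    in a dose raise ``ValueError``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    B = scenario.response.matrix_for(scenario.baseline.taxon_names)
    nutrient_index = {n: k for k, n in enumerate(scenario.response.nutrient_names)}

    pre = ensure_positive(scenario.baseline.values)
    post_clr = clr(pre)
    for i, sample in enumerate(scenario.baseline.sample_ids):
        doses = scenario.nutrient_doses.get(sample, {})
        unknown = set(doses) - set(nutrient_index)
        if unknown:
            raise ValueError(f"unknown nutrients for sample {sample!r}: {sorted(unknown)}")
        eta = np.zeros(len(nutrient_index))
        for name, dose in doses.items():
            eta[nutrient_index[name]] = dose
        shift = B @ eta
        if scenario.noise_sd > 0:
            shift = shift + rng.normal(0.0, scenario.noise_sd, len(shift))
        post_clr[i] = post_clr[i] + shift

    post = clr_inverse(post_clr)
    return AbundanceTable(
        pd.DataFrame(post, index=scenario.baseline.sample_ids,
                     columns=scenario.baseline.taxon_names)
    )
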