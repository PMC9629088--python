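"""Nutrient-composition inversion: from a target microbiome shift to doses.

The mapping from daily micronutrient intake to microbiome modulation is
modeled as a declared linear operator in clr space: a response matrix ``B``
(taxa x nutrients, clr shift per g/day) with per-nutrient dose bounds. The
linear form is a synthetic stand-in for a real nutrient-response database and
is deliberately a swappable, explicit interface. Given the optimizer's
target composition, the recommended doses solve the bounded non-negative
least-squares problem

    min_η ‖B η − Δ‖²   s.t.  0 ≤ η ≤ bounds,   Δ = clr(target) − clr(baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .compositions import clr, clr_inverse, ensure_positive
from .modulation import ModulationParams, ModulationResult, metropolis_search


@dataclass
class NutrientResponseModel:
    """Linear clr-space response of taxa to nutrient doses, with dose bounds."""

    nutrient_names: list[str]
    taxon_names: list[str]
    B: np.ndarray  # rows = taxa, columns = nutrients; clr shift per g/day
    dose_bounds: np.ndarray  # per-nutrient maximum dose, g/day

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.dose_bounds = np.asarray(self.dose_bounds, dtype=float)
        if self.B.shape != (len(self.taxon_names), len(self.nutrient_names)):
            raise ValueError("B must be (n_taxa, n_nutrients)")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("B contains non-finite entries")
        if len(self.dose_bounds) != len(self.nutrient_names):
            raise ValueError("one dose bound per nutrient required")
        if np.any(self.dose_bounds < 0):
            raise ValueError("dose bounds must be non-negative")
        if len(set(self.nutrient_names)) != len(self.nutrient_names):
            raise ValueError("duplicate nutrient names")

    def matrix_for(self, taxon_names) -> np.ndarray:
        """B with rows realigned to the given taxon order."""
        if list(taxon_names) == list(self.taxon_names):
            return self.B
        idx = {t: i for i, t in enumerate(self.taxon_names)}
        missing = [t for t in taxon_names if t not in idx]
        if missing:
            raise ValueError(f"taxon absent from response model: {missing[0]!r}")
        return self.B[[idx[t] for t in taxon_names], :]

    @classmethod
    def random(cls, taxon_names, nutrient_names=None, scale: float = 0.3,
               max_dose: float = 20.0, seed: int = 0, sparsity: float = 0.2,
               signature: dict[str, float] | None = None, n_signature: int = 4,
               ) -> "NutrientResponseModel":
        """A synthetic response model with sparse, centered Gaussian columns.

        Each nutrient acts on a random ~``sparsity`` fraction of taxa with
        clr shifts of magnitude ``scale`` per g/day, mimicking ingredients
        with taxon-specific effects. If a ``signature`` (taxon → weight) is
        given, the first ``n_signature`` nutrients load along ±that direction
        — the analogue of prebiotic-like ingredients curated into a nutrient
        database precisely because they modulate disease-relevant taxa.
        Columns are centered (zero-sum over taxa) so every nutrient's action
        is a valid clr-space direction.
        """
        taxon_names = list(taxon_names)
        if nutrient_names is None:
            nutrient_names = [f"nutrient_{i + 1:02d}" for i in range(16)]
        rng = np.random.default_rng(seed)
        n_taxa, n_nutrients = len(taxon_names), len(nutrient_names)
        B = rng.normal(0.0, scale, (n_taxa, n_nutrients))
        mask = rng.random((n_taxa, n_nutrients)) < sparsity
        B = np.where(mask, B, 0.0)
        if signature:
            s = np.array([signature.get(t, 0.0) for t in taxon_names], dtype=float)
            s -= s.mean()
            norm = np.linalg.norm(s)
            if norm > 0:
                s = s / norm
                for k in range(min(n_signature, n_nutrients)):
                    direction = s if k % 2 == 0 else -s
                    B[:, k] = scale * direction * np.sqrt(n_taxa * sparsity) \
                        + rng.normal(0.0, 0.05 * scale, n_taxa)
        B -= B.mean(axis=0, keepdims=True)
        return cls(
            nutrient_names=list(nutrient_names),
            taxon_names=taxon_names,
            B=B,
            dose_bounds=np.full(n_nutrients, float(max_dose)),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.Series]:
        Bdf = pd.DataFrame(self.B, index=self.taxon_names, columns=self.nutrient_names)
        bounds = pd.Series(self.dose_bounds, index=self.nutrient_names)
        return Bdf, bounds


@dataclass
class NutrientProfile:
    """Recommended daily micronutrient doses (g/day)."""

    doses: dict[str, float]

    def to_series(self) -> pd.Series:
        return pd.Series(self.doses, name="dose_g_per_day")

    def vector(self, nutrient_names) -> np.ndarray:
        return np.array([self.doses.get(n, 0.0) for n in nutrient_names])


def compute_target_shift(baseline, target) -> np.ndarray:
    """Δ = clr(target) − clr(baseline); zero-sum by construction."""
    baseline = ensure_positive(np.asarray(baseline, dtype=float))
    target = ensure_positive(np.asarray(target, dtype=float))
    if baseline.shape != target.shape:
        raise ValueError("baseline and target differ in dimension")
    return clr(target) - clr(baseline)


def recommend_nutrients(delta: np.ndarray, model: NutrientResponseModel
                        ) -> tuple[NutrientProfile, float]:
    """Bounded non-negative least squares inversion of the response model.

    Returns the dose profile and the achieved residual norm ‖Bη − Δ‖.
    Solved with the exact BVLS active-set method, which is deterministic.
    """
    if len(model.nutrient_names) == 0:
        raise ValueError("response model has no nutrients")
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (len(model.taxon_names),):
        raise ValueError(
            f"delta has {delta.shape} entries, model has {len(model.taxon_names)} taxa"
        )
    res = lsq_linear(model.B, delta, bounds=(np.zeros_like(model.dose_bounds),
                                             model.dose_bounds), method="bvls")
    eta = np.clip(res.x, 0.0, model.dose_bounds)  # guard fp drift at active bounds
    residual = float(np.linalg.norm(model.B @ eta - delta))
    profile = NutrientProfile({n: float(d) for n, d in zip(model.nutrient_names, eta)})
    return profile, residual


def design_diet(
    index_model,
    baseline,
    mod_params: ModulationParams,
    response_model: NutrientResponseModel,
) -> tuple[ModulationResult, NutrientProfile, float]:
    """Full per-patient chain: optimize a target, invert nutrients, predict.

    Runs the Metropolis walk toward a lower IBS index, converts the achieved
    shift to recommended doses, and scores the composition those doses are
    predicted to produce: ``clr⁻¹(clr(baseline) + B·η)``.
    """
    result = metropolis_search(index_model, baseline, mod_params)
    delta = compute_target_shift(result.baseline, result.target)
    profile, _residual = recommend_nutrients(delta, response_model)
    eta = profile.vector(response_model.nutrient_names)
    predicted = clr_inverse(clr(result.baseline) + response_model.B @ eta)
    scorer = index_model.score if hasattr(index_model, "score") else index_model
    predicted_post_index = float(scorer(predicted))
    return result, profile, predicted_post_index
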