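"""Metropolis Monte-Carlo search for a minimal microbiome modulation.

Starting from a patient's baseline composition, taxa are perturbed at random
(each selected with a small probability ``p_perturb`` and multiplied by a
log-normal factor), the proposal is re-closed to the simplex and scored by
the IBS-index model, and it is accepted with the Metropolis probability
``min(1, exp((index_current − index_proposed) / temperature))`` — every
index-lowering move is accepted, worsening moves occasionally, which lets the
walk escape flat or locally rugged regions of the tree-ensemble score.
Staying "nearby the baseline" is enforced as a hard Aitchison-distance
budget: proposals beyond the budget are rejected outright. The best accepted
state over the walk is returned as the modulation target.

The walk is an optimizer, not a posterior sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .compositions import aitchison_distance, closure, ensure_positive


@dataclass
class ModulationParams:
    """Knobs of the Metropolis walk.

    p_perturb: per-taxon selection probability per move (dimensionless).
    kernel_sd: SD of the log-scale multiplicative step.
    temperature: Metropolis temperature on the index scale.
    n_iterations: fixed walk length (no convergence heuristic).
    distance_budget: maximum Aitchison distance from baseline; None = unbounded.
    """

    p_perturb: float = 0.1
    kernel_sd: float = 0.25
    temperature: float = 0.02
    n_iterations: int = 2000
    distance_budget: Optional[float] = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p_perturb <= 1:
            raise ValueError("p_perturb must lie in (0, 1]")
        if self.kernel_sd <= 0:
            raise ValueError("kernel_sd must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.distance_budget is not None and self.distance_budget <= 0:
            raise ValueError("distance_budget must be positive or None")


@dataclass
class ModulationResult:
    """Trace and endpoint of one Metropolis walk."""

    baseline: np.ndarray
    target: np.ndarray
    index_trace: np.ndarray  # accepted (current) index after each iteration
    baseline_index: float
    best_index: float
    aitchison_distance: float
    n_accepted: int

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.tolist(),
            "target": self.target.tolist(),
            "index_trace": self.index_trace.tolist(),
            "baseline_index": self.baseline_index,
            "best_index": self.best_index,
            "aitchison_distance": self.aitchison_distance,
            "n_accepted": self.n_accepted,
        }


def perturb(composition: np.ndarray, params: ModulationParams,
            rng: np.random.Generator) -> np.ndarray:
    """One proposal move: multiplicative log-normal kicks on a random taxon subset.

    Each taxon is independently selected with probability ``p_perturb``;
    selected taxa are multiplied by ``exp(N(0, kernel_sd²))`` and the vector
    re-closed. A draw selecting no taxon returns the input unchanged.
    """
    x = np.asarray(composition, dtype=float)
    selected = rng.random(x.shape[-1]) < params.p_perturb
    factors = np.exp(rng.normal(0.0, params.kernel_sd, x.shape[-1]))
    if not selected.any():
        return x.copy()
    return closure(np.where(selected, x * factors, x))


def _as_scorer(model) -> Callable[[np.ndarray], float]:
    if hasattr(model, "score"):
        return lambda x: float(model.score(x))
    if callable(model):
        return lambda x: float(model(x))
    raise TypeError("model must expose .score(composition) or be callable")


def metropolis_search(model, baseline, params: ModulationParams) -> ModulationResult:
    """Run the walk; returns the best accepted composition and its trace.

    ``model`` is an IBS-index model (anything with ``.score`` or a plain
    callable mapping a composition to a real). The baseline is pseudocounted
    once before the walk, so every visited state is strictly positive.
    """
    params.validate()
    score = _as_scorer(model)
    rng = np.random.default_rng(params.seed)

    current = ensure_positive(np.asarray(baseline, dtype=float))
    baseline_pos = current.copy()
    current_index = score(current)
    baseline_index = current_index

    best = current.copy()
    best_index = current_index
    trace = np.empty(params.n_iterations)
    n_accepted = 0

    for it in range(params.n_iterations):
        proposal = perturb(current, params, rng)
        within_budget = (
            params.distance_budget is None
            or aitchison_distance(baseline_pos, proposal) <= params.distance_budget
        )
        if within_budget:
            proposed_index = score(proposal)
            delta = current_index - proposed_index  # > 0 when the proposal improves
            if delta >= 0 or rng.random() < np.exp(delta / params.temperature):
                current = proposal
                current_index = proposed_index
                n_accepted += 1
                if current_index < best_index:
                    best = current.copy()
                    best_index = current_index
        trace[it] = current_index

    return ModulationResult(
        baseline=baseline_pos,
        target=best,
        index_trace=trace,
        baseline_index=float(baseline_index),
        best_index=float(best_index),
        aitchison_distance=aitchison_distance(baseline_pos, best),
        n_accepted=n_accepted,
    )
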