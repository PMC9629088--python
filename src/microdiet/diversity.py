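"""Community-level and per-taxon cohort statistics.

Alpha diversity (Shannon, base 2, plus observed richness), Bray-Curtis and
unweighted UniFrac beta diversity, PERMANOVA on a distance matrix, per-taxon
Mann-Whitney screens with Benjamini-Hochberg correction, and paired-t
machinery for pre/post contrasts. Distance containers are
``skbio.DistanceMatrix``; PERMANOVA and UniFrac delegate to scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.beta import unweighted_unifrac as _skbio_unifrac
from skbio.stats.distance import permanova as _skbio_permanova
from statsmodels.stats.multitest import multipletests

from .compositions import DEFAULT_PSEUDOCOUNT
from .io import AbundanceTable

#: Presence means abundance strictly greater than the pseudocount, so a
#: pseudocounted zero never counts as an observed taxon.
PRESENCE_THRESHOLD = DEFAULT_PSEUDOCOUNT


def shannon(composition) -> float:
    """Shannon diversity in bits: −Σ pᵢ log₂ pᵢ over nonzero parts."""
    p = np.asarray(composition, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance in composition")
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def observed_richness(composition, threshold: float = PRESENCE_THRESHOLD) -> int:
    """Number of taxa with abundance above the presence threshold."""
    p = np.asarray(composition, dtype=float)
    return int((p > threshold).sum())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity: 1 − 2 Σ min(aᵢ, bᵢ) / (Σaᵢ + Σbᵢ)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative abundances")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def unweighted_unifrac(
    a, b, taxa, tree: TreeNode, presence_threshold: float = PRESENCE_THRESHOLD
) -> float:
    """Fraction of tree branch length unique to one of the two communities.

    Presence/absence only: a taxon is present when its abundance exceeds
    ``presence_threshold``. All taxa must be leaves of ``tree``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    taxa = list(taxa)
    tips = {t.name for t in tree.tips()}
    missing = set(taxa) - tips
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    ua = (a > presence_threshold).astype(int)
    ub = (b > presence_threshold).astype(int)
    return float(_skbio_unifrac(ua, ub, taxa=taxa, tree=tree))


def distance_matrix(
    table: AbundanceTable,
    metric: str = "braycurtis",
    tree: TreeNode | None = None,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> DistanceMatrix:
    """Pairwise sample distances. ``metric`` is 'braycurtis' or 'unifrac'."""
    if metric == "braycurtis":
        condensed = pdist(table.values, metric="braycurtis")
        return DistanceMatrix(squareform(condensed), ids=table.sample_ids)
    if metric == "unifrac":
        if tree is None:
            raise ValueError("unifrac requires a tree")
        n = table.n_samples
        vals = np.zeros((n, n))
        X = table.values
        taxa = table.taxon_names
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = unweighted_unifrac(
                    X[i], X[j], taxa, tree, presence_threshold
                )
        return DistanceMatrix(vals, ids=table.sample_ids)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    sample_size: int
    n_groups: int


def permanova(dist: DistanceMatrix, labels, n_permutations: int = 9999, seed: int = 0
              ) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``p = (1 + #{permuted F ≥ observed F}) / (1 + n_permutations)`` — the
    smallest attainable p-value is ``1/(n_permutations + 1)``. Deterministic
    under ``seed``. Every group must contain at least two samples.
    """
    labels = pd.Series(labels, index=list(dist.ids)) if not isinstance(labels, pd.Series) \
        else labels.reindex(list(dist.ids))
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 samples: {list(small.index)}")
    res = _skbio_permanova(dist, labels.to_numpy(), permutations=n_permutations, seed=seed)
    return PermanovaResult(
        pseudo_f=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=int(res["number of permutations"]),
        sample_size=int(res["sample size"]),
        n_groups=int(res["number of groups"]),
    )


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def taxon_screen(table: AbundanceTable, labels) -> pd.DataFrame:
    """Per-taxon two-sided Mann-Whitney U screen between two groups.

    Uses the exact null distribution when both groups have ≤ 8 samples and no
    ties, else the tie-corrected normal approximation (scipy ``method='auto'``).
    Returns a DataFrame (taxon, u_statistic, p_value, q_value, direction) where
    direction is the sign of (group2 median − group1 median) with groups in
    sorted label order. Constant taxa record p = 1.
    """
    labels = pd.Series(labels, index=table.sample_ids) if not isinstance(labels, pd.Series) \
        else labels.reindex(table.sample_ids)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"taxon screen requires exactly two groups, got {groups}")
    g1 = table.values[(labels == groups[0]).to_numpy()]
    g2 = table.values[(labels == groups[1]).to_numpy()]

    rows = []
    for j, taxon in enumerate(table.taxon_names):
        x, y = g1[:, j], g2[:, j]
        if np.ptp(np.concatenate([x, y])) == 0:  # constant across all samples
            u, p = float(len(x) * len(y) / 2.0), 1.0
        else:
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append((taxon, float(u), float(p), float(np.sign(np.median(y) - np.median(x)))))
    out = pd.DataFrame(rows, columns=["taxon", "u_statistic", "p_value", "direction"])
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out[["taxon", "u_statistic", "p_value", "q_value", "direction"]]


@dataclass
class PairedTResult:
    t: float
    p_value: float
    mean_delta: float
    sd_delta: float
    n: int
    degenerate_variance: bool = False


def paired_t(pre_values, post_values) -> PairedTResult:
    """Two-sided paired t test on d = post − pre."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = post - pre
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        if mean_d == 0:
            return PairedTResult(0.0, 1.0, mean_d, sd_d, n)
        # all pairs shifted identically: infinitely strong evidence
        return PairedTResult(float(np.sign(mean_d)) * np.inf, 0.0, mean_d, sd_d, n,
                             degenerate_variance=True)
    t, p = stats.ttest_rel(post, pre)
    return PairedTResult(float(t), float(p), mean_d, sd_d, n)


def paired_t_from_summary(mean_delta: float, sd_delta: float, n: int) -> PairedTResult:
    """Paired t from summary statistics of the differences: t = m/(s/√n)."""
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    if sd_delta <= 0:
        raise ValueError("sd_delta must be positive")
    t = mean_delta / (sd_delta / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), float(p), float(mean_delta), float(sd_delta), int(n))
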