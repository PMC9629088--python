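"""Simplex geometry: closure, pseudocounts, clr transform, Aitchison distance.

Relative-abundance profiles live on the simplex (non-negative, rows sum to 1).
All log-ratio machinery routes through here so the pseudocount policy is
applied in exactly one place: ``1e-6`` added to every part, then re-closure,
before any logarithm is taken.
"""

from __future__ import annotations

import numpy as np

#: Pseudocount added to every part before a log-ratio transform.
DEFAULT_PSEUDOCOUNT = 1e-6


def closure(x: np.ndarray) -> np.ndarray:
    """Rescale the last axis to sum to 1.

    Raises
    ------
    ValueError
        If any entry is negative or a row sums to zero.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("composition has negative entries")
    total = x.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("cannot close an all-zero composition")
    return x / total


def with_pseudocount(x: np.ndarray, eps: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Add ``eps`` to every part and re-close, making the composition strictly positive."""
    return closure(np.asarray(x, dtype=float) + eps)


def ensure_positive(x: np.ndarray, eps: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Close ``x`` and pseudocount only the rows that actually contain zeros.

    Zero-free compositions pass through closure untouched (to float precision),
    so a no-op transform chain reproduces its input; zeros are replaced by the
    standard pseudocount-then-reclose step.
    """
    x = closure(x)
    if x.ndim == 1:
        return with_pseudocount(x, eps) if np.any(x == 0) else x
    has_zero = np.any(x == 0, axis=-1)
    if not has_zero.any():
        return x
    out = x.copy()
    out[has_zero] = with_pseudocount(x[has_zero], eps)
    return out


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform: log(x_i / g(x)) along the last axis.

    Input must be strictly positive (apply :func:`with_pseudocount` first if
    zeros are possible). The result sums to zero along the last axis.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive parts; apply a pseudocount first")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def clr_inverse(z: np.ndarray) -> np.ndarray:
    """Map clr coordinates back to the simplex: closure(exp(z))."""
    z = np.asarray(z, dtype=float)
    # subtract the max for numerical stability before exponentiating
    return closure(np.exp(z - z.max(axis=-1, keepdims=True)))


def aitchison_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between clr(a) and clr(b).

    The natural metric on the simplex; used to quantify how far a modulated
    composition has moved from its baseline.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(clr(a) - clr(b)))
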