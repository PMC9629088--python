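"""Independent brute-force oracles shared by the unit and acceptance suites.

Each oracle re-derives a quantity by exhaustive enumeration or a literal
textbook formula, never by calling the implementation it checks.
"""

import numpy as np


def unifrac_branch_set_oracle(tree, present_a, present_b):
    """Exhaustive branch enumeration: classify every branch by which
    community has a descendant leaf below it; unique / observed length."""
    unique = shared_total = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = {t.name for t in node.tips()} or {node.name}
        in_a = bool(leaves & present_a)
        in_b = bool(leaves & present_b)
        if in_a or in_b:
            shared_total += length
            if in_a != in_b:
                unique += length
    return unique / shared_total if shared_total else 0.0


def bh_stepup_oracle(p):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j >= i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def simplex_grid_min(f, n_parts, step=0.01):
    """Brute-force minimum of f over the step-quantized simplex grid,
    enumerating every integer composition of 1/step quanta into n_parts."""
    k = round(1 / step)
    best = np.inf

    def rec(remaining, parts_left, prefix):
        nonlocal best
        if parts_left == 1:
            best = min(best, f(np.array(prefix + [remaining]) * step))
            return
        for v in range(remaining + 1):
            rec(remaining - v, parts_left - 1, prefix + [v])

    rec(k, n_parts, [])
    return best


def surrogate_index(x):
    """Toy index for optimizer checks: the abundance of the first taxon."""
    return float(np.asarray(x)[0])
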