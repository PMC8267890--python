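"""Independent oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
summation, grid search) and independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pangevo.trees import Tree


def brute_force_parsimony_cost(tree: Tree, leaf_states: dict[str, int],
                               n_states: int, gain: float, loss: float) -> float:
    """Minimum total asymmetric transition cost over all internal labelings."""
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    best = math.inf
    for labeling in itertools.product(range(n_states), repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, labeling)}
        for leaf in tree.leaves():
            state[id(leaf)] = leaf_states[leaf.label]
        cost = 0.0
        for node in tree.postorder():
            if node is tree.root:
                continue
            p, c = state[id(node.parent)], state[id(node)]
            cost += gain * max(0, c - p) + loss * max(0, p - c)
        best = min(best, cost)
    return best


def brute_force_fitch(tree: Tree, leaf_states: dict[str, int],
                      n_states: int = 2) -> int:
    """Minimum number of state changes (unit costs) by enumeration."""
    return int(round(brute_force_parsimony_cost(tree, leaf_states, n_states,
                                                1.0, 1.0)))


def hypergeom_tail(k: int, m: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M=m, K=big_k, n) by direct summation."""
    total = 0.0
    for x in range(k, min(big_k, n) + 1):
        total += (math.comb(big_k, x) * math.comb(m - big_k, n - x)
                  / math.comb(m, n))
    return total


def grid_k_score(t1: Tree, t2: Tree) -> float:
    """Brute-force K score: grid search over the scale factor, refined to 1e-6."""
    f1 = t1.bipartitions(include_trivial=True)
    f2 = t2.bipartitions(include_trivial=True)
    splits = set(f1) | set(f2)
    b1 = np.array([f1.get(s, 0.0) for s in splits])
    b2 = np.array([f2.get(s, 0.0) for s in splits])

    def score(k):
        return float(np.sqrt(((k * b2 - b1) ** 2).sum()))

    lo, hi = 0.0, 10.0
    for _ in range(12):
        ks = np.linspace(lo, hi, 101)
        vals = [score(k) for k in ks]
        i = int(np.argmin(vals))
        lo, hi = ks[max(0, i - 1)], ks[min(100, i + 1)]
    return score((lo + hi) / 2.0)


# ----------------------------- affine-gap alignment score oracle (Gotoh) ----
def gotoh_score(a: str, b: str, matrix, open_gap: float = -11.0,
                extend_gap: float = -1.0) -> float:
    """Optimal global alignment score with free end gaps, by direct DP.

    Matches the scoring of the package's protein aligner (substitution matrix
    plus affine gaps, terminal gaps free).
    """
    n, m = len(a), len(b)
    neg = -1e9
    big_m = np.full((n + 1, m + 1), neg)
    ix = np.full((n + 1, m + 1), neg)   # gap in b (consume a)
    iy = np.full((n + 1, m + 1), neg)   # gap in a (consume b)
    big_m[0, 0] = 0.0
    for i in range(1, n + 1):
        ix[i, 0] = 0.0                  # free leading end gaps
    for j in range(1, m + 1):
        iy[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            big_m[i, j] = max(big_m[i - 1, j - 1], ix[i - 1, j - 1],
                              iy[i - 1, j - 1]) + s
            # a gap of length L scores open + (L-1)*extend
            ix[i, j] = max(big_m[i - 1, j] + open_gap,
                           ix[i - 1, j] + extend_gap,
                           iy[i - 1, j] + open_gap)
            iy[i, j] = max(big_m[i, j - 1] + open_gap,
                           iy[i, j - 1] + extend_gap,
                           ix[i, j - 1] + open_gap)
    # free trailing end gaps: best over last row/column, any matrix
    best = neg
    for i in range(n + 1):
        best = max(best, big_m[i, m], ix[i, m], iy[i, m])
    for j in range(m + 1):
        best = max(best, big_m[n, j], ix[n, j], iy[n, j])
    return float(best)
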