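"""Independent oracles used by the test suite.

Each oracle is coded from first principles, separately from the library
path it checks: a recursive affine-gap local-alignment scorer (and, for
tiny instances, a full path-enumeration scorer), an exact binomial
two-sided p-value by explicit pmf summation, and a random additive-tree
generator for neighbor-joining consistency checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import binom

NEG_INF = float("-inf")


def brute_local_score(a: str, b: str, matrix, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Optimal local-alignment score by an independent recursion.

    States follow the textbook affine-gap formulation: best score of an
    alignment *ending* at (i, j) with the last column a match (M), a gap in
    b (X) or a gap in a (Y); a local alignment may start anywhere (the
    ``max(0, ...)`` restart) and end anywhere.  A gap of length k costs
    ``gap_open + k * gap_extend``.
    """
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def m(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return NEG_INF
        prev = max(0.0, m(i - 1, j - 1), x(i - 1, j - 1), y(i - 1, j - 1))
        return prev + float(matrix[a[i - 1], b[j - 1]])

    @lru_cache(maxsize=None)
    def x(i: int, j: int) -> float:  # a[i-1] against a gap
        if i == 0:
            return NEG_INF
        return max(m(i - 1, j) - first, x(i - 1, j) - gap_extend,
                   y(i - 1, j) - first)

    @lru_cache(maxsize=None)
    def y(i: int, j: int) -> float:  # b[j-1] against a gap
        if j == 0:
            return NEG_INF
        return max(m(i, j - 1) - first, x(i, j - 1) - first,
                   y(i, j - 1) - gap_extend)

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, m(i, j), x(i, j), y(i, j))
    return best


def enumerate_local_score(a: str, b: str, matrix, gap_open: float = 11.0,
                          gap_extend: float = 1.0) -> float:
    """True enumeration of every local alignment path (tiny inputs only).

    Depth-first search over all monotone move sequences (diagonal, up,
    left) from every start cell, with affine gap accounting; exponential,
    so only usable for sequences of length <= ~7.
    """
    first = gap_open + gap_extend
    best = 0.0
    sub = {(ca, cb): float(matrix[ca, cb]) for ca in set(a) for cb in set(b)}

    def dfs(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            dfs(i + 1, j + 1, score + sub[(a[i], b[j])], "M")
        if i < len(a):
            cost = gap_extend if last == "X" else first
            dfs(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if last == "Y" else first
            dfs(i, j + 1, score - cost, "Y")

    for i in range(len(a)):
        for j in range(len(b)):
            dfs(i + 1, j + 1, sub[(a[i], b[j])], "M")
    return best


def exact_binom_two_sided(k: int, n: int, p: float) -> float:
    """Doubled-smaller-tail exact binomial p-value by pmf summation."""
    if n == 0:
        return 1.0
    lower = sum(float(binom.pmf(i, n, p)) for i in range(0, k + 1))
    upper = sum(float(binom.pmf(i, n, p)) for i in range(k, n + 1))
    return min(1.0, 2.0 * min(lower, upper))


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths; returns
    (skbio TreeNode, labels, path-length matrix)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        del nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode()
        parent.extend([a, b])
        nodes.append(parent)
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    root = TreeNode()
    root.extend(nodes)
    tt = root.tip_tip_distances()
    labels = tuple(tt.ids)
    d = np.asarray(tt.data, dtype=float)
    return root, labels, d
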