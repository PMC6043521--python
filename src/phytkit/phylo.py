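"""Distance-based phylogenetics: protein distances, neighbor joining,
Newick serialization, clade assignment.

Distances come from an existing multiple sequence alignment (pairwise
deletion of gapped sites; optional Kimura correction for multiple hits).
Tree building is Saitou–Nei neighbor joining, which is consistent on
additive matrices: leaf-to-leaf path lengths of the output reproduce an
additive input matrix exactly.  Trees are held as ``skbio.TreeNode`` with a
trifurcating root (the conventional representation of an unrooted binary
tree) and serialized as Newick.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if np.any(np.abs(self.d - self.d.T) > 1e-12):
            raise ValueError("matrix must be symmetric within 1e-12")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)


# p >= this value makes the Kimura log argument non-positive
_KIMURA_MAX_P = (np.sqrt(1 + 4 / 0.8) - 1) / (2 / 0.8)  # ~0.8541


def pairwise_distances(
    msa: Mapping[str, str] | Sequence[tuple[str, str]],
    correction: str = "none",
) -> DistanceMatrix:
    """Pairwise protein distances from an alignment.

    ``p`` is the mismatch fraction over sites where both rows are non-gap
    (pairwise deletion).  ``correction="kimura"`` applies the Kimura
    protein-distance correction ``d = -ln(1 - p - 0.2 p^2)``; ``"none"``
    keeps ``d = p``.
    """
    items = list(msa.items()) if isinstance(msa, Mapping) else list(msa)
    if len(items) < 2:
        raise ValueError("an alignment needs at least 2 rows")
    labels = [k for k, _ in items]
    seqs = [s for _, s in items]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned rows must have equal length")
    if correction not in ("none", "kimura"):
        raise ValueError(f"unknown correction {correction!r}")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    nongap = arr != b"-"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"rows {labels[i]!r} and {labels[j]!r} share no non-gap sites"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / n_shared
            if correction == "kimura":
                if p >= _KIMURA_MAX_P:
                    raise ValueError(
                        f"rows {labels[i]!r}/{labels[j]!r}: p = {p:.4f} is too "
                        "large for the Kimura correction; use correction='none'"
                    )
                dist = -np.log(1.0 - p - 0.2 * p * p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=tuple(labels), d=d)


def _clamp(length: float, sister: float, clamp: bool) -> tuple[float, float]:
    # move a negative branch's deficit to its sister edge (total conserved)
    if clamp and length < 0:
        return 0.0, sister + length
    return length, sister


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` (row sums r), with branch
    lengths from the standard two-point formulas, closing the tree with a
    three-way join.  Ties in Q are broken by the smallest (i, j) index
    pair.  Negative branch lengths are clamped to 0 with the deficit moved
    to the sister edge (toggle with ``clamp_negative``).

    ``n = 2`` returns the single edge split at its midpoint; ``n < 2`` is
    rejected.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    if n == 2:
        half = dm.d[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        root = TreeNode()
        root.extend(nodes)
        return root
    d = dm.d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin over the full matrix in row-major order finds the smallest
        # (i, j) among ties; symmetry guarantees i < j for the first hit
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj, clamp_negative)
        lj, li = _clamp(lj, li, clamp_negative)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        d_new = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([
            np.hstack([[0.0], d_new[keep]]),
            np.hstack([d_new[keep][:, None], d[np.ix_(keep, keep)]]),
        ])
        nodes = [parent] + [nodes[k] for k in keep]
    # final three-way join by the three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = max(0.0, length) if clamp_negative else length
    root = TreeNode()
    root.extend([a, b, c])
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree as a Newick string with branch lengths."""
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a tree."""
    return TreeNode.read(_io.StringIO(newick))


def patristic_distances(tree: TreeNode):
    """Leaf-to-leaf path-length matrix (skbio DistanceMatrix)."""
    return tree.tip_tip_distances()


def assign_clades(
    tree: TreeNode, labeled_leaves: Mapping[str, str]
) -> dict[str, str]:
    """Assign each unlabeled leaf the subfamily of its nearest labeled leaf
    by patristic distance; ties break by lexicographic leaf label.
    Labeled leaves map to their own subfamily."""
    if not labeled_leaves:
        raise ValueError("at least one labeled leaf is required")
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    unknown = set(labeled_leaves) - set(ids)
    if unknown:
        raise ValueError(f"labeled leaves not in tree: {sorted(unknown)}")
    refs = sorted(labeled_leaves)
    out: dict[str, str] = {}
    for leaf in ids:
        if leaf in labeled_leaves:
            out[leaf] = labeled_leaves[leaf]
            continue
        best = min(refs, key=lambda r: (dm[leaf, r], r))
        out[leaf] = labeled_leaves[best]
    return out
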