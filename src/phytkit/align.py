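"""Smith–Waterman local alignment with affine gaps.

Replaces the heuristic BLAST retrieval step of the original family screen
with exact local alignment: scores are the optimum over all local
alignments under BLOSUM62 (by default) with BLAST-style affine gap costs,
where a gap of length k costs ``gap_open + k * gap_extend`` (defaults 11/1,
the canonical protein-BLAST parameters).

The dynamic programming engine is Biopython's ``PairwiseAligner`` (local
mode); this module fixes the scoring conventions, the treatment of unknown
residues (``X`` scores as the worst value in the partner's matrix column —
conservative), and exposes the coordinate bookkeeping the screening and
junction-calling modules need.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .types import AMINO_ACIDS


@lru_cache(maxsize=None)
def default_matrix():
    """BLOSUM62 with X rescored to the per-column worst canonical value."""
    m = substitution_matrices.load("BLOSUM62").copy()
    canon = list(AMINO_ACIDS)
    worst_overall = min(float(m[a, b]) for a in canon for b in canon)
    for a in m.alphabet:
        if a == "X":
            continue
        worst = min(float(m[b, a]) for b in canon)
        m["X", a] = worst
        m[a, "X"] = worst
    m["X", "X"] = worst_overall
    return m


@dataclass(frozen=True)
class LocalAlignment:
    """Result of one local alignment.

    ``target_blocks``/``query_blocks`` are parallel lists of half-open
    intervals: the i-th target block aligns gaplessly to the i-th query
    block.  An empty alignment (all pair scores negative) has score 0 and
    no blocks.
    """

    score: float
    target_blocks: tuple[tuple[int, int], ...]
    query_blocks: tuple[tuple[int, int], ...]

    @property
    def is_empty(self) -> bool:
        return not self.target_blocks

    @property
    def target_span(self) -> Optional[tuple[int, int]]:
        if self.is_empty:
            return None
        return (self.target_blocks[0][0], self.target_blocks[-1][1])

    @property
    def query_span(self) -> Optional[tuple[int, int]]:
        if self.is_empty:
            return None
        return (self.query_blocks[0][0], self.query_blocks[-1][1])

    def query_coverage(self, query_length: int) -> float:
        """Fraction of query residues inside aligned (non-gap) columns."""
        aligned = sum(e - s for s, e in self.query_blocks)
        return aligned / query_length if query_length else 0.0

    def map_query_to_target(self, q_pos: int) -> Optional[int]:
        """Target position aligned to query position, or None if in a gap
        or outside the local alignment footprint."""
        for (ts, _te), (qs, qe) in zip(self.target_blocks, self.query_blocks):
            if qs <= q_pos < qe:
                return ts + (q_pos - qs)
        return None


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: str,
    target: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal local alignment of ``query`` against ``target``.

    Returns the maximum local-alignment score and one optimal alignment
    (Biopython's deterministic first traceback).  When no residue pair
    scores positively the Smith–Waterman optimum is the empty alignment
    with score 0.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    if matrix is None:
        matrix = default_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = float(aligner.score(target, query))
    if score <= 0:
        return LocalAlignment(score=0.0, target_blocks=(), query_blocks=())
    aln = aligner.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    return LocalAlignment(
        score=score,
        target_blocks=tuple((int(s), int(e)) for s, e in t_blocks),
        query_blocks=tuple((int(s), int(e)) for s, e in q_blocks),
    )


def self_score(sequence: str, matrix=None) -> float:
    """Ungapped score of a sequence against itself (the diagonal sum)."""
    if matrix is None:
        matrix = default_matrix()
    return float(sum(matrix[a, a] for a in sequence))
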