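"""Prodomain-junction calling and phytaspase classification.

The prodomain of plant subtilases is removed autocatalytically, so the
sequence at the prodomain junction reflects the enzyme's own cleavage
preference.  Junctions are called by mapping the known junction of an
annotated reference through the best local alignment; each called junction
yields a P6..P1|P1'..P6' window.  Candidates are subtilases with Asp at P1,
subtyped by the residue homologous to His331 of tobacco phytaspase (the S1
substrate-pocket residue): His-, Lys- or Gly-type.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .align import LocalAlignment, local_align
from .types import (
    AMINO_ACIDS,
    PAD,
    CleavageWindow,
    JunctionCall,
    JunctionUncallableError,
    PhytaspaseCall,
    ProteinRecord,
    ReferenceJunction,
)


def extract_window(sequence: str, cut_index: int) -> CleavageWindow:
    """The 12-mer window around the bond before ``cut_index``.

    ``cut_index`` is the 0-based index of the first residue on the prime
    side (P1'); P1 is ``sequence[cut_index - 1]``.  Positions outside the
    sequence are padded with ``-``.  A cut at 0 or at the sequence length
    has no residue on one side of the bond and is rejected.
    """
    n = len(sequence)
    if not (0 < cut_index < n):
        raise ValueError(f"cut_index must lie strictly inside (0, {n}), got {cut_index}")
    left = sequence[max(0, cut_index - 6):cut_index].rjust(6, PAD)
    right = sequence[cut_index:cut_index + 6].ljust(6, PAD)
    return CleavageWindow(residues=left + right)


def _map_with_gap_fallback(
    aln: LocalAlignment, ref_pos: int, query_len: int
) -> tuple[Optional[int], bool]:
    """Map a reference position through ``aln``; when it falls in a gap,
    fall back to the nearest aligned reference position on the mature
    (C-terminal) side.  Returns (query position, used_fallback)."""
    pos = aln.map_query_to_target(ref_pos)
    if pos is not None:
        return pos, False
    span = aln.query_span
    if span is None or not (span[0] <= ref_pos < span[1]):
        return None, False
    for r in range(ref_pos + 1, span[1]):
        pos = aln.map_query_to_target(r)
        if pos is not None:
            # shift back so the mapped index keeps the same distance to the
            # first mature residue that anchored it
            return max(1, pos - (r - ref_pos)), True
    return None, False


def call_junction(
    protein: ProteinRecord,
    references: Sequence[ReferenceJunction],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[JunctionCall, Optional[str]]:
    """Call the prodomain junction of ``protein`` via reference alignment.

    Each reference is locally aligned to the protein; among references
    whose junction falls inside the aligned region, the highest-scoring one
    (ties: lexicographic reference id) anchors the call.  Returns the
    junction call together with the mapped residue-331 (or None when the
    reference lacks one or it maps into a gap).

    Raises :class:`JunctionUncallableError` when no reference alignment
    covers any junction.
    """
    if not references:
        raise ValueError("at least one annotated reference is required")
    best: Optional[tuple[float, str, ReferenceJunction, LocalAlignment]] = None
    for ref in sorted(references, key=lambda r: r.id):
        aln = local_align(
            ref.sequence, protein.sequence, gap_open=gap_open, gap_extend=gap_extend
        )
        if aln.is_empty:
            continue
        span = aln.query_span
        if span is None or not (span[0] <= ref.junction_index < span[1]):
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, ref.id, ref, aln)
    if best is None:
        raise JunctionUncallableError(
            f"{protein.id}: no reference alignment covers a junction"
        )
    score, _, ref, aln = best
    warnings: list[str] = []
    junction, in_gap = _map_with_gap_fallback(
        aln, ref.junction_index, len(protein.sequence)
    )
    if junction is None:
        raise JunctionUncallableError(
            f"{protein.id}: junction column unmappable through reference {ref.id}"
        )
    if in_gap:
        warnings.append("junction_in_gap")
    window = extract_window(protein.sequence, junction)
    if window.residues[6:8] != "TT":
        # the invariant Thr-Thr at P1'/P2' marks the mature N terminus of
        # plant subtilases; its absence is suspicious but not disqualifying
        warnings.append("no_thr_thr_prime")
    residue331: Optional[str] = None
    if ref.res331_index is not None:
        pos = aln.map_query_to_target(ref.res331_index)
        if pos is not None:
            residue331 = protein.sequence[pos]
    call = JunctionCall(
        protein_id=protein.id,
        junction_index=junction,
        window=window,
        anchor_reference_id=ref.id,
        mapping_score=score,
        warnings=tuple(warnings),
    )
    return call, residue331


_SUBTYPE_BY_RESIDUE = {"H": "His-type", "K": "Lys-type", "G": "Gly-type"}


def classify_phytaspase(
    junction_call: JunctionCall, residue331: Optional[str]
) -> PhytaspaseCall:
    """Asp-P1 / residue-331 classification of one junction call.

    A candidate phytaspase carries Asp at P1.  Candidates are subtyped by
    the mapped residue-331: His-, Lys- or Gly-type, otherwise ``other``
    (including an unmappable residue-331).
    """
    is_candidate = junction_call.window.p1 == "D"
    if not is_candidate:
        subtype = "non-candidate"
    else:
        subtype = _SUBTYPE_BY_RESIDUE.get(residue331 or "", "other")
    return PhytaspaseCall(
        protein_id=junction_call.protein_id,
        is_candidate=is_candidate,
        residue331=residue331,
        subtype=subtype,
    )
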