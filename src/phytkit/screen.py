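"""Subtilase family screening: domain annotation, completeness filter,
tandem-array detection.

The screen mirrors how the tomato subtilase family was curated: candidate
proteins are annotated by local alignment against an S8 (peptidase-domain)
reference and an I9 (prodomain) reference, then filtered for completeness —
length between 650 and 800 residues inclusive, all four catalytic residues
of the S8 domain present, and an I9 prodomain present.  Gene coordinates of
retained family members can then be clustered into tandem arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import LocalAlignment, local_align, self_score
from .anchors import CATALYTIC_OFFSETS, CATALYTIC_RESIDUES, I9_ANCHOR, S8_ANCHOR
from .types import DomainArchitecture, GeneCoordinate, ProteinRecord


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the family screen, all overridable.

    A domain is deemed present when its local-alignment score reaches
    ``score_fraction`` of the reference's ungapped self-score and the
    alignment covers at least ``min_coverage`` of the reference.
    """

    min_length: int = 650
    max_length: int = 800
    score_fraction: float = 0.5
    min_coverage: float = 0.6
    gap_open: float = 11.0
    gap_extend: float = 1.0


DEFAULT_CONFIG = ScreenConfig()


def _domain_hit(
    ref: str, protein: ProteinRecord, config: ScreenConfig
) -> tuple[bool, LocalAlignment]:
    aln = local_align(
        ref, protein.sequence, gap_open=config.gap_open, gap_extend=config.gap_extend
    )
    present = (
        not aln.is_empty
        and aln.score >= config.score_fraction * self_score(ref)
        and aln.query_coverage(len(ref)) >= config.min_coverage
    )
    return present, aln


def annotate_architecture(
    protein: ProteinRecord,
    s8_ref: str = S8_ANCHOR,
    i9_ref: str = I9_ANCHOR,
    catalytic_offsets: Sequence[int] = CATALYTIC_OFFSETS,
    catalytic_residues: str = CATALYTIC_RESIDUES,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> DomainArchitecture:
    """Annotate S8/I9 presence and catalytic machinery of one protein.

    Catalytic positions are the protein positions aligned to the designated
    reference positions; a position is recorded only when the protein
    carries the identical residue there.  Absence of a domain is encoded,
    never raised.
    """
    s8_present, s8_aln = _domain_hit(s8_ref, protein, config)
    cat_positions: list[int] = []
    if s8_present:
        for off, res in zip(catalytic_offsets, catalytic_residues):
            pos = s8_aln.map_query_to_target(off)
            if pos is not None and protein.sequence[pos] == res:
                cat_positions.append(pos)
    i9_present, i9_aln = _domain_hit(i9_ref, protein, config)
    return DomainArchitecture(
        protein_id=protein.id,
        s8_present=s8_present,
        s8_span=s8_aln.target_span if s8_present else None,
        s8_score=s8_aln.score,
        catalytic_positions=tuple(cat_positions),
        i9_present=i9_present,
        i9_span=i9_aln.target_span if i9_present else None,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the completeness filter."""

    retained: tuple[str, ...]
    exclusions: dict[str, str]  # protein_id -> first failing criterion

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def completeness_filter(
    proteins: Iterable[ProteinRecord],
    architectures: dict[str, DomainArchitecture],
    config: ScreenConfig = DEFAULT_CONFIG,
    n_catalytic: int = len(CATALYTIC_OFFSETS),
) -> ScreenResult:
    """Retain apparently full-length subtilases.

    A protein is retained iff its length lies in
    [``min_length``, ``max_length``] (inclusive), all ``n_catalytic``
    catalytic residues of the S8 domain were found, and the I9 prodomain is
    present.  The exclusion report records the first failing criterion in
    that order.  Output is sorted by protein id, hence invariant to input
    order, and the operation is idempotent.
    """
    retained: list[str] = []
    exclusions: dict[str, str] = {}
    for protein in sorted(proteins, key=lambda p: p.id):
        arch = architectures[protein.id]
        if not (config.min_length <= len(protein) <= config.max_length):
            exclusions[protein.id] = "length"
        elif len(arch.catalytic_positions) < n_catalytic:
            exclusions[protein.id] = "catalytic"
        elif not arch.i9_present:
            exclusions[protein.id] = "i9"
        else:
            retained.append(protein.id)
    return ScreenResult(retained=tuple(retained), exclusions=exclusions)


def find_tandem_arrays(
    coords: Sequence[GeneCoordinate], max_gap_kb: float = 100.0
) -> list[tuple[GeneCoordinate, ...]]:
    """Cluster same-chromosome family genes into tandem arrays.

    A cluster is a maximal run of genes on one chromosome in which
    consecutive gene start positions differ by at most ``max_gap_kb``
    kilobases.  Singletons are reported as size-1 clusters.
    """
    seen: set[str] = set()
    for c in coords:
        if c.gene_id in seen:
            raise ValueError(f"duplicate gene_id {c.gene_id!r}")
        seen.add(c.gene_id)
    max_gap_bp = max_gap_kb * 1000.0
    ordered = sorted(coords, key=lambda c: (c.chromosome, c.start, c.gene_id))
    clusters: list[list[GeneCoordinate]] = []
    for gene in ordered:
        if (
            clusters
            and clusters[-1][-1].chromosome == gene.chromosome
            and gene.start - clusters[-1][-1].start <= max_gap_bp
        ):
            clusters[-1].append(gene)
        else:
            clusters.append([gene])
    return [tuple(c) for c in clusters]
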