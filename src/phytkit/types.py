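"""Shared domain types for the subtilase/phytaspase analysis pipeline.

The carriers defined here are deliberately small: plain dataclasses with
validation in ``__post_init__``, so every downstream module can rely on the
stated invariants without re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical amino acids, alphabetical one-letter codes."""

PAD: str = "-"
"""Pad symbol used at sequence-boundary positions of cleavage windows."""

#: Schechter–Berger position labels for a 12-residue cleavage window,
#: six non-prime positions upstream and six prime positions downstream
#: of the scissile bond.
WINDOW_POSITIONS: tuple[str, ...] = (
    "P6", "P5", "P4", "P3", "P2", "P1",
    "P1'", "P2'", "P3'", "P4'", "P5'", "P6'",
)


class GenerationError(ValueError):
    """Raised when a synthetic construct cannot be assembled as requested."""


class JunctionUncallableError(ValueError):
    """Raised when no reference alignment covers a prodomain junction."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: identifier, residues, optional description.

    ``X`` is tolerated on input (unknown residue in real proteome releases)
    and flagged via :attr:`has_unknown`; generators never emit it.
    """

    id: str
    sequence: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        allowed = set(AMINO_ACIDS + "X")
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def has_unknown(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageWindow:
    """The 12 residues P6..P1 | P1'..P6' around one scissile bond.

    Boundary positions that fall outside the source sequence carry the pad
    symbol ``-``.  P1 (index 5) must be a real residue for any window that
    is classified downstream.
    """

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != 12:
            raise ValueError(f"window must have 12 symbols, got {len(self.residues)}")
        allowed = set(AMINO_ACIDS + "X" + PAD)
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(f"invalid window symbols {sorted(bad)}")

    @property
    def p1(self) -> str:
        return self.residues[5]

    @property
    def nonprime(self) -> str:
        return self.residues[:6]

    @property
    def prime(self) -> str:
        return self.residues[6:]

    def __str__(self) -> str:
        return f"{self.nonprime}|{self.prime}"


@dataclass(frozen=True)
class DomainArchitecture:
    """Domain annotation of one protein: S8 footprint, catalytic machinery, I9.

    ``catalytic_positions`` holds the protein indices aligned to the four
    designated catalytic residues of the S8 reference (the Asp/His/Asn/Ser
    machinery) — only those that align to the identical residue are recorded.
    """

    protein_id: str
    s8_present: bool
    s8_span: Optional[tuple[int, int]] = None  # 0-based half-open
    s8_score: float = 0.0
    catalytic_positions: tuple[int, ...] = ()
    i9_present: bool = False
    i9_span: Optional[tuple[int, int]] = None
    pa_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if list(self.catalytic_positions) != sorted(set(self.catalytic_positions)):
            raise ValueError("catalytic_positions must be strictly increasing")
        if self.catalytic_positions and self.s8_span is not None:
            lo, hi = self.s8_span
            for p in self.catalytic_positions:
                if not (lo <= p < hi):
                    raise ValueError("catalytic position outside s8_span")


@dataclass(frozen=True)
class GeneCoordinate:
    """1-based inclusive gene coordinates, as carried by GFF3."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class JunctionCall:
    """A called prodomain junction: first mature residue and its window."""

    protein_id: str
    junction_index: int  # 0-based index of the first mature residue
    window: CleavageWindow
    anchor_reference_id: str
    mapping_score: float
    warnings: tuple[str, ...] = ()


SUBTYPES = ("His-type", "Lys-type", "Gly-type", "other", "non-candidate")


@dataclass(frozen=True)
class PhytaspaseCall:
    """Asp-P1 / residue-331 classification of one curated subtilase.

    A candidate carries Asp at P1 of the prodomain junction; the subtype is
    read from the residue homologous to position 331 of tobacco phytaspase
    (His/Lys/Gly-type, or ``other`` when the residue is anything else or
    could not be mapped).
    """

    protein_id: str
    is_candidate: bool
    residue331: Optional[str]
    subtype: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if (self.subtype == "non-candidate") != (not self.is_candidate):
            raise ValueError("subtype is non-candidate iff is_candidate is false")
        mapping = {"H": "His-type", "K": "Lys-type", "G": "Gly-type"}
        if self.is_candidate:
            expected = mapping.get(self.residue331 or "", "other")
            if self.subtype != expected:
                raise ValueError(
                    f"subtype {self.subtype!r} inconsistent with residue331 "
                    f"{self.residue331!r}"
                )


@dataclass(frozen=True)
class FluorescenceTrace:
    """A fluorogenic-substrate time course in relative fluorescence units."""

    times: tuple[float, ...]  # minutes, strictly increasing
    values: tuple[float, ...]
    enzyme: Optional[str] = None
    substrate: Optional[str] = None
    ph: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least 2 points")
        import numpy as np

        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RateEstimate:
    """OLS initial-rate estimate for one trace."""

    slope: float
    intercept: float
    r_squared: float
    window: tuple[int, int]  # point-index half-open interval used for the fit
    unit: str = "per_min"  # per_min | per_hour


@dataclass
class ReferenceJunction:
    """An annotated reference protein used to anchor junction calling.

    ``junction_index`` is the 0-based index of the first mature residue;
    ``res331_index`` the 0-based index of the residue playing the role of
    His331 (tobacco-phytaspase numbering) in the S1 pocket, or None.
    """

    id: str
    sequence: str
    junction_index: int
    res331_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.junction_index < len(self.sequence)):
            raise ValueError(f"reference {self.id!r}: junction outside sequence")
        if self.res331_index is not None and not (
            0 <= self.res331_index < len(self.sequence)
        ):
            raise ValueError(f"reference {self.id!r}: res331 outside sequence")
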