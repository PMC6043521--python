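"""In-silico PICS: proteome digestion, specificity-model cleavage, and
cleavage-site reconstruction from prime-side fragments.

PICS (proteomic identification of protease cleavage sites) profiles a
protease by digesting a peptide library, capturing the C-terminal (prime
side) fragments of cleaved peptides, and reconstructing the full
P6..P1|P1'..P6' site by looking each fragment up in the library.  Here the
wet steps are replaced by a ground-truth specificity model: a 12-position
by 20-letter additive score matrix over the cleavage window, cleaving
either deterministically above a score cutoff or stochastically through a
logistic link.  Because simulation records the true window of every event,
the reconstruction step can be validated exactly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .junctions import extract_window
from .logo import AA_INDEX, BackgroundFrequencies, PositionalEnrichment, positional_enrichment
from .types import AMINO_ACIDS, PAD, CleavageWindow, ProteinRecord, WINDOW_POSITIONS

#: Residues cleaved after, per enzyme; both block cleavage before proline.
ENZYME_RULES = {
    "trypsin": frozenset("KR"),
    "chymotrypsin": frozenset("FYWL"),
}


@dataclass(frozen=True)
class DigestionRules:
    """Cleave-after digestion rules with peptide length bounds."""

    cleave_after: frozenset[str]
    block_before_proline: bool = True
    min_len: int = 8
    max_len: int = 30
    enzyme: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")

    @classmethod
    def for_enzyme(cls, enzyme: str, min_len: int = 8, max_len: int = 30,
                   block_before_proline: bool = True) -> "DigestionRules":
        if enzyme not in ENZYME_RULES:
            raise ValueError(f"unknown enzyme {enzyme!r}; choose from {sorted(ENZYME_RULES)}")
        return cls(cleave_after=ENZYME_RULES[enzyme], min_len=min_len,
                   max_len=max_len, block_before_proline=block_before_proline,
                   enzyme=enzyme)


@dataclass(frozen=True)
class Peptide:
    sequence: str
    source_protein_id: str
    source_offset: int  # 0-based offset within the source protein


@dataclass
class PeptideLibrary:
    """Digested peptide library with a proper-suffix index for fragment
    lookup (the reconstruction step's database)."""

    peptides: list[Peptide]
    _suffix_index: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._suffix_index:
            index: dict[str, list[int]] = defaultdict(list)
            for i, pep in enumerate(self.peptides):
                # proper suffixes only: a prime fragment always has at least
                # one upstream residue in its source peptide
                for cut in range(1, len(pep.sequence)):
                    index[pep.sequence[cut:]].append(i)
            self._suffix_index = dict(index)

    def lookup(self, fragment: str) -> list[int]:
        return self._suffix_index.get(fragment, [])

    def __len__(self) -> int:
        return len(self.peptides)


def digest(proteome: Iterable[ProteinRecord], rules: DigestionRules,
           apply_length_filter: bool = True) -> PeptideLibrary:
    """Exhaustive digestion with zero missed cleavages.

    The backbone is cut after every residue in ``cleave_after`` except when
    the following residue is proline (if ``block_before_proline``).
    Fragments outside [``min_len``, ``max_len``] are dropped unless
    ``apply_length_filter`` is disabled (useful for reassembly checks).
    """
    peptides: list[Peptide] = []
    for record in proteome:
        seq = record.sequence
        start = 0
        for i, aa in enumerate(seq):
            cut_here = aa in rules.cleave_after and (
                not rules.block_before_proline
                or i + 1 >= len(seq)
                or seq[i + 1] != "P"
            )
            if cut_here or i == len(seq) - 1:
                frag = seq[start:i + 1]
                if not apply_length_filter or rules.min_len <= len(frag) <= rules.max_len:
                    peptides.append(Peptide(frag, record.id, start))
                start = i + 1
    return PeptideLibrary(peptides=peptides)


@dataclass(frozen=True)
class SpecificityModel:
    """Additive cleavage-preference model over the 12-position window.

    ``weights`` is a (12, 20) log-odds-scale score matrix (rows P6..P6',
    columns the canonical amino acids); a bond's score is the sum of
    weights over its window, pad positions contributing 0.  ``threshold``
    mode cleaves deterministically at ``score >= tau``; ``bernoulli`` mode
    cleaves with probability ``logistic(steepness * (score - tau))``.
    """

    weights: np.ndarray
    mode: str = "threshold"
    tau: float = 0.0
    steepness: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (12, 20):
            raise ValueError("weights must have shape (12, 20)")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if self.mode not in ("threshold", "bernoulli"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")
        object.__setattr__(self, "weights", w)

    def score_window(self, window: CleavageWindow | str) -> float:
        residues = window.residues if isinstance(window, CleavageWindow) else window
        total = 0.0
        for i, aa in enumerate(residues):
            if aa == PAD:
                continue
            j = AA_INDEX.get(aa)
            if j is not None:
                total += self.weights[i, j]
        return float(total)

    @classmethod
    def asp_p1(cls, reward: float = 10.0, penalty: float = -10.0,
               tau: float = 5.0, mode: str = "threshold",
               extra: Optional[dict[tuple[str, str], float]] = None,
               steepness: float = 1.0) -> "SpecificityModel":
        """Strict Asp-P1 model: ``reward`` for D at P1, ``penalty`` for any
        other P1 residue, 0 elsewhere; ``extra`` adds (position, residue)
        weights, e.g. ``{("P4", "I"): 2.0}``."""
        w = np.zeros((12, 20))
        p1 = WINDOW_POSITIONS.index("P1")
        w[p1, :] = penalty
        w[p1, AA_INDEX["D"]] = reward
        for (pos, aa), value in (extra or {}).items():
            w[WINDOW_POSITIONS.index(pos), AA_INDEX[aa]] += value
        return cls(weights=w, mode=mode, tau=tau, steepness=steepness)


@dataclass(frozen=True)
class CleavageEvent:
    peptide_index: int
    cut_index: int        # bond before this 0-based index within the peptide
    score: float
    prime_fragment: str
    true_window: CleavageWindow


def simulate_cleavage(
    library: PeptideLibrary,
    model: SpecificityModel,
    seed: int = 0,
    min_prime_len: int = 4,
) -> list[CleavageEvent]:
    """Cleave each library peptide under the specificity model.

    Every internal bond is scored; in threshold mode bonds with
    ``score >= tau`` fire, in bernoulli mode each bond fires independently
    with its logistic probability (seeded).  At most one cut per peptide is
    retained — the highest-scoring fired bond, leftmost on ties — and
    events whose prime fragment is shorter than ``min_prime_len`` residues
    (unidentifiable by MS) are dropped.
    """
    rng = np.random.default_rng(seed)
    events: list[CleavageEvent] = []
    for idx, pep in enumerate(library.peptides):
        seq = pep.sequence
        best: Optional[tuple[float, int]] = None
        for cut in range(1, len(seq)):
            window = extract_window(seq, cut)
            score = model.score_window(window)
            if model.mode == "threshold":
                fired = score >= model.tau
            else:
                prob = 1.0 / (1.0 + np.exp(-model.steepness * (score - model.tau)))
                fired = rng.random() < prob
            if fired and (best is None or score > best[0]):
                best = (score, cut)
        if best is None:
            continue
        score, cut = best
        prime = seq[cut:]
        if len(prime) < min_prime_len:
            continue
        events.append(CleavageEvent(
            peptide_index=idx,
            cut_index=cut,
            score=score,
            prime_fragment=prime,
            true_window=extract_window(seq, cut),
        ))
    return events


@dataclass(frozen=True)
class ReconstructionResult:
    windows: tuple[CleavageWindow, ...]
    n_ambiguous: int
    n_unmatched: int

    @property
    def n_retained(self) -> int:
        return len(self.windows)


def reconstruct_sites(
    prime_fragments: Sequence[str], library: PeptideLibrary
) -> ReconstructionResult:
    """Rebuild cleavage windows from prime-side fragments by library lookup.

    Each fragment must occur as a proper suffix of exactly one library
    peptide; the window is rebuilt from that peptide around the inferred
    bond (non-prime residues from upstream peptide context, pads at the
    peptide boundary).  Fragments with zero or multiple hits are discarded
    and counted.
    """
    windows: list[CleavageWindow] = []
    n_ambiguous = n_unmatched = 0
    for fragment in prime_fragments:
        hits = library.lookup(fragment)
        if len(hits) == 1:
            pep = library.peptides[hits[0]]
            cut = len(pep.sequence) - len(fragment)
            windows.append(extract_window(pep.sequence, cut))
        elif len(hits) == 0:
            n_unmatched += 1
        else:
            n_ambiguous += 1
    return ReconstructionResult(
        windows=tuple(windows), n_ambiguous=n_ambiguous, n_unmatched=n_unmatched
    )


def specificity_profile(
    windows: Sequence[CleavageWindow],
    background: BackgroundFrequencies,
    alpha: float = 0.05,
) -> PositionalEnrichment:
    """Positional enrichment of reconstructed PICS windows vs background."""
    if not windows:
        raise ValueError("no windows left after ambiguity filtering")
    return positional_enrichment(windows, background, alpha=alpha,
                                 provenance="pics")
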