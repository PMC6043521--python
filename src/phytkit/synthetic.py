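"""Seeded generators for every input class the pipeline consumes.

Each generator returns its artifact together with a ground-truth record, so
downstream modules (screening, junction calling, enrichment statistics,
PICS, assay quantification, necrosis scoring) can be tested offline against
known answers.  All generators are bit-reproducible under a fixed seed and
emit only the 20 canonical amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .anchors import (
    CATALYTIC_OFFSETS,
    I9_ANCHOR,
    I9_END_GAP,
    S8_ANCHOR,
    S8_START_GAP,
    RES331_ANCHOR_OFFSET,
)
from .types import AMINO_ACIDS, GenerationError, ProteinRecord

UNIFORM_FREQS: tuple[float, ...] = tuple([0.05] * 20)

#: Approximate amino-acid composition of a plant (Arabidopsis-like) proteome,
#: ordered as :data:`phytkit.types.AMINO_ACIDS`; normalized to sum to 1.
PLANT_LIKE_FREQS: tuple[float, ...] = tuple(
    (np.array(
        [6.3, 1.8, 5.4, 6.7, 4.2, 6.4, 2.3, 5.4, 6.4, 9.5,
         2.4, 4.5, 4.7, 3.5, 5.4, 9.0, 5.1, 6.9, 1.25, 2.9]
    ) / np.array(
        [6.3, 1.8, 5.4, 6.7, 4.2, 6.4, 2.3, 5.4, 6.4, 9.5,
         2.4, 4.5, 4.7, 3.5, 5.4, 9.0, 5.1, 6.9, 1.25, 2.9]
    ).sum()).tolist()
)


def _check_freqs(aa_freqs) -> np.ndarray:
    f = np.asarray(aa_freqs, dtype=float)
    if f.shape != (20,):
        raise ValueError("aa_freqs must have exactly 20 entries")
    if np.any(f < 0):
        raise ValueError("aa_freqs entries must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"aa_freqs must sum to 1 (got {f.sum():.12f})")
    return f


@dataclass(frozen=True)
class BackgroundSpec:
    """Background proteome: i.i.d. residues from a 20-letter composition."""

    n_proteins: int
    length_range: tuple[int, int] = (200, 600)
    aa_freqs: tuple[float, ...] = UNIFORM_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        lo, hi = self.length_range
        if lo < 1 or lo > hi:
            raise ValueError("length_range must satisfy 1 <= lo <= hi")
        _check_freqs(self.aa_freqs)


@dataclass(frozen=True)
class PlantedSbtSpec:
    """A synthetic subtilase with controllable junction and diagnostics.

    Sequence layout, relative to ``junction_index`` j (0-based index of the
    first mature residue): the I9 anchor at [j-70, j-10), the 12-mer
    ``window_residues`` at [j-6, j+6), the S8 anchor at [j+30, j+180) with
    the residue-331 analog at j+95.  Everything else is background-random.
    """

    id: str
    total_length: int
    junction_index: int
    p1_residue: str = "D"
    window_residues: Optional[str] = None  # default built from p1_residue
    residue331_analog: str = "H"
    has_i9: bool = True
    has_catalytic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (6 <= self.junction_index <= self.total_length - 6):
            raise ValueError("junction_index must lie in [6, total_length - 6]")
        if self.p1_residue not in AMINO_ACIDS:
            raise ValueError(f"invalid p1_residue {self.p1_residue!r}")
        if self.residue331_analog not in AMINO_ACIDS:
            raise ValueError(f"invalid residue331_analog {self.residue331_analog!r}")
        w = self.window()
        if len(w) != 12 or any(c not in AMINO_ACIDS for c in w):
            raise ValueError("window_residues must be 12 canonical residues")
        if w[5] != self.p1_residue:
            raise ValueError("window_residues[5] must equal p1_residue")

    def window(self) -> str:
        if self.window_residues is not None:
            return self.window_residues
        # Default junction context: invariant Thr-Thr at P1'/P2', the mark of
        # the mature subtilase amino terminus.
        return "STQAV" + self.p1_residue + "TTHGAA"


@dataclass(frozen=True)
class SbtTruth:
    """Ground-truth sidecar for one planted subtilase."""

    protein_id: str
    junction_index: int
    p1_residue: str
    residue331_analog: str
    residue331_index: int
    window_residues: str
    has_i9: bool
    has_catalytic: bool
    i9_span: Optional[tuple[int, int]]
    s8_span: tuple[int, int]
    catalytic_positions: tuple[int, ...]

    @property
    def is_candidate(self) -> bool:
        return self.p1_residue == "D"


@dataclass(frozen=True)
class TraceSpec:
    """Linear-plus-Gaussian-noise fluorescence trace."""

    intercept: float = 0.0
    slope: float = 1.0          # fluorescence units per minute
    noise_sd: float = 0.0
    n_points: int = 30
    dt: float = 1.0             # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LeafImageSpec:
    """Synthetic scanned-leaf image: white scanner background, gray leaf
    disc, planted dark (necrotic) pixels."""

    width: int = 100
    height: int = 100
    leaf_fraction: float = 0.5
    necrotic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if not (0 < self.leaf_fraction <= 1):
            raise ValueError("leaf_fraction must be in (0, 1]")
        if not (0 <= self.necrotic_fraction <= 1):
            raise ValueError("necrotic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LeafTruth:
    n_leaf: int
    n_dark: int


def _random_residues(rng: np.random.Generator, n: int, freqs) -> str:
    letters = rng.choice(list(AMINO_ACIDS), size=n, p=np.asarray(freqs, float))
    return "".join(letters)


def make_background_proteome(spec: BackgroundSpec) -> list[ProteinRecord]:
    """Draw ``n_proteins`` random proteins with i.i.d. residues."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_residues(rng, length, spec.aa_freqs)
        records.append(ProteinRecord(id=f"bg{i:05d}", sequence=seq))
    return records


def make_planted_sbt(
    spec: PlantedSbtSpec, background: BackgroundSpec | None = None
) -> tuple[ProteinRecord, SbtTruth]:
    """Assemble one synthetic subtilase and its truth annotation.

    Raises :class:`GenerationError` when the junction window would collide
    with an anchor segment or fall outside the sequence.
    """
    freqs = background.aa_freqs if background is not None else UNIFORM_FREQS
    _check_freqs(freqs)
    j = spec.junction_index
    n = spec.total_length
    i9_span = (j - I9_END_GAP - len(I9_ANCHOR), j - I9_END_GAP)
    s8_span = (j + S8_START_GAP, j + S8_START_GAP + len(S8_ANCHOR))
    if spec.has_i9 and i9_span[0] < 0:
        raise GenerationError(
            f"{spec.id}: no room for the I9 anchor upstream of junction {j}"
        )
    if s8_span[1] > n:
        raise GenerationError(
            f"{spec.id}: S8 anchor [{s8_span[0]}, {s8_span[1]}) exceeds "
            f"total_length {n}"
        )
    # Window occupies [j-6, j+6); anchors by construction end 4 residues
    # before it and start 24 after it, so collisions can only arise from a
    # junction too close to the termini (caught above).
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_residues(rng, n, freqs))
    if spec.has_i9:
        seq[i9_span[0]:i9_span[1]] = I9_ANCHOR
    s8 = list(S8_ANCHOR)
    if not spec.has_catalytic:
        for off in CATALYTIC_OFFSETS:
            s8[off] = "A"
    s8[RES331_ANCHOR_OFFSET] = spec.residue331_analog
    seq[s8_span[0]:s8_span[1]] = s8
    seq[j - 6:j + 6] = spec.window()
    record = ProteinRecord(id=spec.id, sequence="".join(seq))
    truth = SbtTruth(
        protein_id=spec.id,
        junction_index=j,
        p1_residue=spec.p1_residue,
        residue331_analog=spec.residue331_analog,
        residue331_index=s8_span[0] + RES331_ANCHOR_OFFSET,
        window_residues=spec.window(),
        has_i9=spec.has_i9,
        has_catalytic=spec.has_catalytic,
        i9_span=i9_span if spec.has_i9 else None,
        s8_span=s8_span,
        catalytic_positions=tuple(
            s8_span[0] + off for off in CATALYTIC_OFFSETS
        ) if spec.has_catalytic else (),
    )
    return record, truth


def make_trace(spec: TraceSpec):
    """Linear fluorescence time course with optional Gaussian noise."""
    from .types import FluorescenceTrace

    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points) * spec.dt
    v = spec.intercept + spec.slope * t
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    return FluorescenceTrace(times=tuple(t.tolist()), values=tuple(v.tolist()))


def make_leaf_image(spec: LeafImageSpec) -> tuple[np.ndarray, LeafTruth]:
    """8-bit grayscale leaf scan with an exact planted dark-pixel count.

    Background is pure white (255), leaf pixels mid-gray in [100, 160],
    necrotic pixels dark in [10, 40].  The leaf is the ``n_leaf`` pixels
    closest to the image center (a compact disc); exactly
    ``round(necrotic_fraction * n_leaf)`` of them are darkened.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n_pixels = h * w
    n_leaf = max(1, int(round(spec.leaf_fraction * n_pixels)))
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    leaf_idx = order[:n_leaf]
    img = np.full(n_pixels, 255, dtype=np.uint8)
    img[leaf_idx] = rng.integers(100, 161, size=n_leaf)
    n_dark = int(round(spec.necrotic_fraction * n_leaf))
    if n_dark > 0:
        dark_idx = rng.choice(leaf_idx, size=n_dark, replace=False)
        img[dark_idx] = rng.integers(10, 41, size=n_dark)
    return img.reshape(h, w), LeafTruth(n_leaf=n_leaf, n_dark=n_dark)
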