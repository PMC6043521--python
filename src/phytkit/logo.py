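"""Positional amino-acid enrichment of cleavage windows vs a background.

This module computes the numbers behind consensus "iceLogo"-style displays:
for each window position (P6..P6') and each of the 20 amino acids, the
sample frequency among aligned windows is compared with the amino acid's
natural abundance in a background proteome.  Letter height is the percent
difference ``100 * (sample_freq - bg_freq)``, shown only where it differs
significantly from natural abundance (two-sided exact binomial test,
default alpha 0.05, no multiple-testing correction).

Pad symbols at boundary positions reduce the per-position sample size
rather than counting as a 21st letter; ``X`` is excluded from background
counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .types import AMINO_ACIDS, PAD, CleavageWindow, ProteinRecord, WINDOW_POSITIONS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Amino-acid composition of a background proteome."""

    freq: tuple[float, ...]  # 20 entries, ordered as AMINO_ACIDS
    n_residues_used: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freq)
        if f.shape != (20,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("freq must be 20 nonnegative entries summing to 1")

    def __getitem__(self, aa: str) -> float:
        return self.freq[AA_INDEX[aa]]


def background_frequencies(proteome: Iterable[ProteinRecord]) -> BackgroundFrequencies:
    """Per-amino-acid frequency over all canonical residues of a proteome.

    ``X`` residues are excluded from both numerator and denominator.
    """
    counts = np.zeros(20, dtype=np.int64)
    for record in proteome:
        for aa in record.sequence:
            idx = AA_INDEX.get(aa)
            if idx is not None:
                counts[idx] += 1
    total = int(counts.sum())
    if total == 0:
        raise ValueError("proteome contains no canonical residues")
    return BackgroundFrequencies(freq=tuple((counts / total).tolist()),
                                 n_residues_used=total)


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value, doubled-smaller-tail convention:
    ``min(1, 2 * min(P(X <= k), P(X >= k)))`` for X ~ Binomial(n, p)."""
    if n == 0:
        return 1.0
    lower = binom.cdf(k, n, p)
    upper = binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class PositionalEnrichment:
    """Per-(position, amino acid) enrichment layers, each of shape (12, 20).

    Rows follow :data:`phytkit.types.WINDOW_POSITIONS`, columns
    :data:`phytkit.types.AMINO_ACIDS`.
    """

    sample_count: np.ndarray      # int, residue counts per cell
    n_per_position: np.ndarray    # int, non-pad windows per position
    sample_freq: np.ndarray
    bg_freq: np.ndarray
    percent_difference: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray       # bool
    alpha: float
    n_windows: int
    provenance: str = "windows"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position, amino_acid and all layers."""
        rows = []
        for i, pos in enumerate(WINDOW_POSITIONS):
            for j, aa in enumerate(AMINO_ACIDS):
                rows.append({
                    "position": pos,
                    "amino_acid": aa,
                    "sample_count": int(self.sample_count[i, j]),
                    "n": int(self.n_per_position[i]),
                    "sample_freq": self.sample_freq[i, j],
                    "bg_freq": self.bg_freq[i, j],
                    "percent_difference": self.percent_difference[i, j],
                    "p_value": self.p_value[i, j],
                    "significant": bool(self.significant[i, j]),
                })
        return pd.DataFrame(rows)


def positional_enrichment(
    windows: Sequence[CleavageWindow],
    bg: BackgroundFrequencies,
    alpha: float = 0.05,
    provenance: str = "windows",
) -> PositionalEnrichment:
    """Exact-binomial positional enrichment of windows against ``bg``.

    Per cell, the count of amino acid *a* at position *pos* out of the
    non-pad windows at that position is tested against ``bg.freq[a]`` with
    the two-sided exact binomial test; the effect size is the percent
    difference ``100 * (sample_freq - bg_freq)``.
    """
    if not windows:
        raise ValueError("at least one window is required")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    counts = np.zeros((12, 20), dtype=np.int64)
    n_pos = np.zeros(12, dtype=np.int64)
    for w in windows:
        for i, aa in enumerate(w.residues):
            if aa == PAD:
                continue
            idx = AA_INDEX.get(aa)
            if idx is None:  # X: counts toward neither letter nor n
                continue
            counts[i, idx] += 1
            n_pos[i] += 1
    bg_freq = np.tile(np.asarray(bg.freq), (12, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        sample_freq = np.where(n_pos[:, None] > 0, counts / n_pos[:, None], 0.0)
    percent_difference = 100.0 * (sample_freq - bg_freq)
    p_value = np.ones((12, 20), dtype=float)
    for i in range(12):
        n = int(n_pos[i])
        if n == 0:
            continue
        for j in range(20):
            p_value[i, j] = binom_two_sided(int(counts[i, j]), n, bg_freq[i, j])
    significant = p_value < alpha
    return PositionalEnrichment(
        sample_count=counts,
        n_per_position=n_pos,
        sample_freq=sample_freq,
        bg_freq=bg_freq,
        percent_difference=percent_difference,
        p_value=p_value,
        significant=significant,
        alpha=alpha,
        n_windows=len(windows),
        provenance=provenance,
    )


def logo_matrix(enrichment: PositionalEnrichment) -> np.ndarray:
    """Signed letter heights (12 x 20): the percent difference where
    significant, 0 elsewhere.  Positive heights are enrichments (above the
    axis in a rendered logo), negative heights depletions."""
    return np.where(enrichment.significant, enrichment.percent_difference, 0.0)


def render_logo(enrichment: PositionalEnrichment, path) -> None:
    """Convenience matplotlib rendering of the signed height matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = logo_matrix(enrichment)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    for i, pos in enumerate(WINDOW_POSITIONS):
        up = down = 0.0
        order = np.argsort(-np.abs(heights[i]))
        for j in order:
            h = heights[i, j]
            if h == 0:
                continue
            if h > 0:
                ax.text(i, up + h / 2, AMINO_ACIDS[j], ha="center", va="center",
                        fontsize=6 + min(10, abs(h) / 8), color="tab:green")
                up += h
            else:
                ax.text(i, down + h / 2, AMINO_ACIDS[j], ha="center", va="center",
                        fontsize=6 + min(10, abs(h) / 8), color="tab:red")
                down += h
    ax.set_xticks(range(12), WINDOW_POSITIONS)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("% difference vs background")
    ax.set_xlim(-0.5, 11.5)
    lim = max(10.0, np.abs(heights).sum(axis=1).max())
    ax.set_ylim(-lim, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
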