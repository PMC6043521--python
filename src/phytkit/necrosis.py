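"""Necrotic-lesion quantification from scanned leaf images, and the
unpaired t-test used to compare treatment groups.

Cell death in stained leaves is quantified as the percentage of dark
pixels within the leaf mask: the near-white scanner background is removed
with a white threshold, then dark (necrotic) pixels are separated from
healthy leaf tissue either by Otsu's method computed within the mask
(default) or by a fixed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class NecrosisResult:
    leaf_pixels: int
    dark_pixels: int
    percent_necrotic: float
    white_threshold: float
    dark_threshold: float

    def __post_init__(self) -> None:
        if self.dark_pixels > self.leaf_pixels:
            raise ValueError("dark_pixels cannot exceed leaf_pixels")


def necrotic_fraction(
    image: np.ndarray,
    white_threshold: float = 250.0,
    dark_policy: Union[str, float] = "otsu",
) -> NecrosisResult:
    """Percent dark pixels within the leaf mask of a scanned leaf.

    RGB images are averaged to grayscale.  The leaf mask is every pixel
    strictly below ``white_threshold`` (scanner background removal); dark
    pixels are leaf pixels at or below the dark threshold — Otsu's
    threshold computed within the mask when ``dark_policy="otsu"``, or the
    given fixed value.  An empty leaf mask is an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    elif img.ndim != 2:
        raise ValueError("image must be single-channel or RGB")
    mask = img < white_threshold
    leaf_pixels = int(mask.sum())
    if leaf_pixels == 0:
        raise ValueError("empty leaf mask: no pixels below the white threshold")
    if dark_policy == "otsu":
        dark_threshold = float(threshold_otsu(img[mask]))
    else:
        dark_threshold = float(dark_policy)
    dark_pixels = int((img[mask] <= dark_threshold).sum())
    return NecrosisResult(
        leaf_pixels=leaf_pixels,
        dark_pixels=dark_pixels,
        percent_necrotic=100.0 * dark_pixels / leaf_pixels,
        white_threshold=float(white_threshold),
        dark_threshold=dark_threshold,
    )


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def unpaired_ttest(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Two-sample unpaired t-test (pooled variance by default).

    The classic equal-variance Student t; ``welch=True`` switches to the
    Welch unequal-variance form.  Zero pooled variance with equal means
    returns p = 1 by convention; with different means it is an error (an
    infinite t statistic).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    na, nb = len(x), len(y)
    ma, mb = float(x.mean()), float(y.mean())
    va, vb = float(x.var(ddof=1)), float(y.var(ddof=1))
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if ma == mb:
                t_stat, df, p = 0.0, float(na + nb - 2), 1.0
            else:
                raise ValueError("zero variance with unequal means")
        else:
            t_stat = (ma - mb) / np.sqrt(se2)
            df = se2 ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
            p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    else:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        if pooled == 0:
            if ma == mb:
                t_stat, p = 0.0, 1.0
            else:
                raise ValueError("zero pooled variance with unequal means")
        else:
            t_stat = (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return GroupComparison(
        mean_a=ma, mean_b=mb, sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        n_a=na, n_b=nb, t_statistic=float(t_stat),
        degrees_of_freedom=float(df), p_value=float(p),
    )
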