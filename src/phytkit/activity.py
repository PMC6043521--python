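"""Quantification of fluorogenic-substrate protease assays.

Initial rates are ordinary least-squares slopes of fluorescence traces
(relative fluorescence units per minute, or per hour when configured);
pH profiles are expressed as percent of the maximum activity at the pH
optimum; substrate panels are normalized per enzyme; and peptide substrates
are scored under a cleavage-specificity model, linking profile and panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .logo import AA_INDEX
from .pics import SpecificityModel
from .types import PAD, FluorescenceTrace, RateEstimate, WINDOW_POSITIONS


def _ols(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(t) == 0:
        raise ValueError("degenerate times: zero variance")
    slope, intercept = np.polyfit(t, v, 1)
    resid = v - (slope * t + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def initial_rate(
    trace: FluorescenceTrace,
    window_policy: str = "best_prefix",
    min_frac: float = 0.3,
    fixed_window: Optional[tuple[int, int]] = None,
    unit: str = "per_min",
) -> RateEstimate:
    """OLS initial-rate estimate for one trace.

    Policies: ``best_prefix`` (default) fits every contiguous prefix
    covering at least ``min_frac`` of the points and keeps the best-r²
    one (ties: more points); ``full`` uses the whole trace; ``fixed``
    uses ``fixed_window`` (point-index half-open interval).
    Slopes are per minute; ``unit="per_hour"`` rescales by 60.
    """
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.values, dtype=float)
    n = len(t)
    if window_policy == "fixed":
        if fixed_window is None:
            raise ValueError("fixed policy requires fixed_window")
        lo, hi = fixed_window
        if not (0 <= lo < hi <= n) or hi - lo < 2:
            raise ValueError("fixed_window must select >= 2 points inside the trace")
        candidates = [(lo, hi)]
    elif window_policy == "full":
        candidates = [(0, n)]
    elif window_policy == "best_prefix":
        k_min = max(2, int(np.ceil(min_frac * n)))
        candidates = [(0, k) for k in range(k_min, n + 1)]
    else:
        raise ValueError(f"unknown window_policy {window_policy!r}")
    best: Optional[tuple[float, int, tuple]] = None
    for lo, hi in candidates:
        slope, intercept, r2 = _ols(t[lo:hi], v[lo:hi])
        key = (r2, hi - lo)
        if best is None or key > best[:2]:
            best = (r2, hi - lo, (slope, intercept, r2, (lo, hi)))
    slope, intercept, r2, window = best[2]
    if unit == "per_hour":
        slope, intercept = slope * 60.0, intercept
    elif unit != "per_min":
        raise ValueError(f"unknown unit {unit!r}")
    return RateEstimate(slope=slope, intercept=intercept, r_squared=r2,
                        window=window, unit=unit)


@dataclass(frozen=True)
class PhProfile:
    percent_of_max: dict[float, float]
    optimum_ph: float


def ph_profile(rates: Mapping[float, float]) -> PhProfile:
    """Percent-of-maximum activity per pH, and the pH optimum.

    The optimum is the measured pH with the highest slope (no
    interpolation); ties go to the lower pH.  All slopes non-positive is an
    error.
    """
    if len(rates) < 2:
        raise ValueError("a pH profile needs at least 2 pH points")
    max_rate = max(rates.values())
    if max_rate <= 0:
        raise ValueError("all slopes are non-positive; no pH optimum")
    percent = {ph: 100.0 * slope / max_rate for ph, slope in rates.items()}
    optimum = min((ph for ph, s in rates.items() if s == max_rate))
    return PhProfile(percent_of_max=percent, optimum_ph=optimum)


def panel_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Normalize an enzyme (rows) x substrate (columns) rate matrix.

    Returns a long-format table with raw rates, percent of the enzyme's
    maximum, and the per-enzyme top substrate (argmax; lexicographic ties;
    None and a flag when an enzyme's rates are all zero).
    """
    if rates.empty:
        raise ValueError("empty rate matrix")
    rows = []
    for enzyme, row in rates.iterrows():
        max_rate = row.max()
        if max_rate > 0:
            top = min(row.index[row == max_rate])
            undefined = False
        else:
            top, undefined = None, True
        for substrate in sorted(rates.columns):
            raw = float(row[substrate])
            rows.append({
                "enzyme": enzyme,
                "substrate": substrate,
                "rate": raw,
                "percent_of_max": 100.0 * raw / max_rate if max_rate > 0 else np.nan,
                "top_substrate": top,
                "top_undefined": undefined,
            })
    return pd.DataFrame(rows)


def score_peptide(model: SpecificityModel, peptide: str) -> float:
    """Score a fluorogenic peptide substrate under a specificity model.

    For AFC conjugates the peptide's C-terminal residue occupies P1 (the
    fluorophore sits on the prime side), so the last six residues fill
    P6..P1 — padded on the left for shorter peptides — and the prime-side
    positions are missing and contribute 0.
    """
    if not peptide:
        raise ValueError("empty peptide")
    nonprime = peptide[-6:].rjust(6, PAD)
    total = 0.0
    for i, aa in enumerate(nonprime):
        if aa == PAD:
            continue
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"invalid residue {aa!r} in peptide")
        total += model.weights[i, j]
    return float(total)
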