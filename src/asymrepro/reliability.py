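"""Test-retest reliability (ICC) and rank-correlation correlates.

The intraclass correlation is computed from the mean squares of a
subjects x sessions two-way decomposition.  The default is the
absolute-agreement single-measurement ICC from the two-way random-effects
model (ICC(A,1)): scan-rescan with possible scanner drift is an
absolute-agreement question.  The consistency variant (ICC(C,1)) is
available and insensitive to a constant session offset.

Rank correlations (Spearman) relate regional properties — measurement
reliability and regional size — to asymmetry effect sizes and
reproducibility rates across the 34 cortical regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCRecord",
    "RegionProfile",
    "icc",
    "spearman",
    "regional_correlates",
]


@dataclass(frozen=True)
class ICCRecord:
    """Test-retest reliability of one regional metric."""

    region: str
    metric: str
    icc: float
    n_subjects: int
    model: str = "absolute"  # "absolute" (ICC(A,1)) or "consistency" (ICC(C,1))

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("ICC needs at least 2 subjects")
        if self.icc > 1.0 + 1e-12:
            raise ValueError(f"ICC cannot exceed 1, got {self.icc}")


@dataclass(frozen=True)
class RegionProfile:
    """Per-region bundle of size, effect sizes, rates, and reliabilities."""

    region: str
    mean_size: float
    effect_size_thickness: float
    effect_size_area: float
    rate_thickness: float
    rate_area: float
    icc_thickness: float
    icc_area: float

    def __post_init__(self):
        if self.mean_size <= 0:
            raise ValueError(f"mean_size must be positive, got {self.mean_size}")


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of an n_subjects x k_sessions two-way layout."""
    n, k = x.shape
    grand = x.mean()
    msr = k * float(((x.mean(axis=1) - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((x.mean(axis=0) - grand) ** 2).sum()) / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    mse = float((resid ** 2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    test: Sequence[float],
    retest: Sequence[float],
    model: str = "absolute",
    region: str = "",
    metric: str = "",
) -> ICCRecord:
    """Single-measurement test-retest ICC from a two-session design.

    ``model="absolute"``: two-way random effects, absolute agreement,
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    ``model="consistency"``: ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE).
    """
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("test and retest must be equal-length vectors")
    if t.size < 2:
        raise ValueError("ICC needs at least 2 subjects")
    x = np.stack([t, r], axis=1)
    if np.ptp(x) == 0.0:
        raise ValueError("zero total variance: all measurements identical")
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    if model == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if denom == 0.0:
        raise ValueError("zero between- plus within-subject variance")
    return ICCRecord(
        region=region or "unnamed",
        metric=metric or "unnamed",
        icc=float((msr - mse) / denom),
        n_subjects=n,
        model=model,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


_PAIRINGS = [
    ("mean_size", "effect_size_thickness"),
    ("mean_size", "effect_size_area"),
    ("mean_size", "rate_thickness"),
    ("mean_size", "rate_area"),
    ("icc_thickness", "effect_size_thickness"),
    ("icc_area", "effect_size_area"),
    ("icc_thickness", "rate_thickness"),
    ("icc_area", "rate_area"),
]


def regional_correlates(profiles: Sequence[RegionProfile]) -> pd.DataFrame:
    """Spearman correlations of regional size and ICC with |effect| and rate.

    One row per (x, y) pairing across regions; effect sizes enter as
    magnitudes (direction is irrelevant to how big an asymmetry is).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 regions")
    for p in profiles:
        for name in (
            "mean_size",
            "effect_size_thickness",
            "effect_size_area",
            "rate_thickness",
            "rate_area",
            "icc_thickness",
            "icc_area",
        ):
            value = getattr(p, name)
            if value is None or not np.isfinite(value):
                raise ValueError(f"region {p.region!r}: missing field {name!r}")
    frame = pd.DataFrame(
        {
            "mean_size": [p.mean_size for p in profiles],
            "effect_size_thickness": [abs(p.effect_size_thickness) for p in profiles],
            "effect_size_area": [abs(p.effect_size_area) for p in profiles],
            "rate_thickness": [p.rate_thickness for p in profiles],
            "rate_area": [p.rate_area for p in profiles],
            "icc_thickness": [p.icc_thickness for p in profiles],
            "icc_area": [p.icc_area for p in profiles],
        }
    )
    rows = []
    for xcol, ycol in _PAIRINGS:
        rho, p_val = spearman(frame[xcol].to_numpy(), frame[ycol].to_numpy())
        rows.append({"x": xcol, "y": ycol, "rho": rho, "p": p_val, "n_regions": len(profiles)})
    return pd.DataFrame(rows)
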