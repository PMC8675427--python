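"""Analytic power for the paired t-test, directional power, and PPV.

Power uses the exact noncentral-t formulation: under a true standardized
paired effect d at sample size n, the paired t statistic follows a
noncentral t distribution with df = n-1 and noncentrality delta = d*sqrt(n).
Directional power is the probability of rejecting in the tail whose sign
matches the true effect — the quantity that drives reproduction of a
significant pooled effect.

The positive predictive value follows Ioannidis' formula
PPV = (1-beta) R / ((1-beta) R + alpha), with R the prestudy odds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from asymrepro.effects import EffectRecord
from asymrepro.meta import MetaResult

__all__ = [
    "PowerQuery",
    "paired_t_power",
    "directional_power",
    "ppv",
    "power_table",
    "power_grid",
]


@dataclass(frozen=True)
class PowerQuery:
    """A power/PPV query: true effect d, sample size n, level alpha."""

    d: float
    n: int
    alpha: float = 0.05
    two_sided: bool = True
    R: float = 1.0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.R < 0:
            raise ValueError(f"prestudy odds R must be >= 0, got {self.R}")


def paired_t_power(
    d: float, n: int, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """P(reject H0) for the paired t-test under true standardized effect d.

    Two-sided by default; the one-sided variant rejects in the upper tail.
    At d = 0 the value equals alpha exactly (the size of the test).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    df = n - 1
    if two_sided:
        # symmetric in d; keep the noncentrality nonnegative so the far-tail
        # term is the one that may underflow (scipy yields nan there)
        ncp = abs(d) * math.sqrt(n)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        near = float(stats.nct.sf(tcrit, df, ncp))
        far = float(stats.nct.cdf(-tcrit, df, ncp))
        if math.isnan(far):
            far = 0.0
        return near + far
    ncp = d * math.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def directional_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Probability of a correct-direction rejection at two-sided level alpha.

    This is the per-dataset probability of reproducing a significant pooled
    effect of the same sign as d: the t statistic must land in the rejection
    tail matching sign(d).  By convention d = 0 returns alpha/2 (either tail
    is "wrong", so exactly one tail's mass counts).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    if d == 0.0:
        return alpha / 2.0
    ncp = abs(d) * math.sqrt(n)
    # Correct tail is the one matching sign(d); by symmetry compute for d > 0.
    return float(stats.nct.sf(tcrit, df, ncp))


def ppv(power: float, R: float, alpha: float = 0.05) -> float:
    """Positive predictive value (1-beta)R / ((1-beta)R + alpha)."""
    if not 0.0 <= power <= 1.0:
        raise ValueError(f"power must lie in [0,1], got {power}")
    if R < 0:
        raise ValueError(f"prestudy odds R must be >= 0, got {R}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    numer = power * R
    if numer == 0.0:
        warnings.warn(
            "ppv: (1-beta)*R is zero (no power or zero prestudy odds); PPV is 0",
            stacklevel=2,
        )
        return 0.0
    return numer / (numer + alpha)


def power_table(
    meta: MetaResult,
    records: Sequence[EffectRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-dataset classification with analytic power at the pooled effect.

    Each dataset is classified from its own result (significant positive /
    significant negative / nonsignificant at ``alpha``); the power column is
    the two-sided paired-t power to detect the pooled effect size at that
    dataset's n.
    """
    if not records:
        raise ValueError("no effect records supplied")
    rows = []
    for rec in records:
        if rec.p <= alpha:
            label = "significant positive" if rec.d > 0 else "significant negative"
        else:
            label = "nonsignificant"
        rows.append(
            {
                "measure_id": rec.measure_id,
                "dataset_id": rec.dataset_id,
                "n": rec.n,
                "d": rec.d,
                "p": rec.p,
                "classification": label,
                "power_at_pooled_d": paired_t_power(meta.pooled_d, rec.n, alpha),
            }
        )
    return pd.DataFrame(rows)


def power_grid(
    d_values: Sequence[float],
    n_values: Sequence[int],
    alpha_values: Sequence[float] = (0.05,),
) -> pd.DataFrame:
    """Power landscape over a (d, n, alpha) grid (two-sided paired t-test)."""
    rows = [
        {
            "d": float(d),
            "n": int(n),
            "alpha": float(a),
            "power": paired_t_power(d, n, a),
            "directional_power": directional_power(d, n, a),
        }
        for d in d_values
        for n in n_values
        for a in alpha_values
    ]
    return pd.DataFrame(rows)
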