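"""Per-dataset paired left-right effects.

For each dataset and measure the hemispheric effect is the within-subject
left-minus-right contrast, tested with a paired t-test and summarized as the
paired-samples standardized mean difference

    d_z = mean(L - R) / SD(L - R) = t / sqrt(n),

with large-sample sampling variance ``var_d = 1/n + d^2/(2n)``.  The sign
convention is left minus right throughout, so positive ``d`` means a leftward
asymmetry.  No small-sample (Hedges) correction is applied unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from asymrepro.errors import DegenerateSampleError

__all__ = [
    "PairedMeasurements",
    "EffectRecord",
    "DatasetMeta",
    "paired_effect",
    "paired_effect_from_differences",
    "effect_from_t",
    "hedges_correction",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Left and right measurements of one measure for one dataset.

    Units are whatever the measure carries (mm for thickness, mm^2 for area);
    they cancel in the standardized effect.
    """

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self):
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        if left.ndim != 1 or right.ndim != 1:
            raise ValueError("left and right must be one-dimensional vectors")
        if left.shape != right.shape:
            raise ValueError(
                f"left and right have different lengths ({left.size} vs {right.size})"
            )
        if left.size < 2:
            raise ValueError("paired samples need at least 2 subjects")
        if not (np.isfinite(left).all() and np.isfinite(right).all()):
            raise ValueError("measurements must be finite")

    @property
    def differences(self) -> np.ndarray:
        return self.left - self.right

    @property
    def n(self) -> int:
        return int(self.left.size)


@dataclass(frozen=True)
class EffectRecord:
    """One dataset's paired left-right effect for one measure."""

    dataset_id: str
    measure_id: str
    n: int
    t: float
    d: float
    var_d: float
    p: float
    df: int
    mean_diff: float | None = None
    sd_diff: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.df != self.n - 1:
            raise ValueError(f"df must equal n-1 ({self.n - 1}), got {self.df}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.var_d <= 0:
            raise ValueError(f"var_d must be positive, got {self.var_d}")


@dataclass(frozen=True)
class DatasetMeta:
    """Dataset-level metadata used for subgroup analyses."""

    dataset_id: str
    n: int
    field_strength: float = 3.0
    fs_version: str = "5.3"
    age_min: float = 18.0
    age_max: float = 90.0
    site: str = ""

    def __post_init__(self):
        if self.age_min > self.age_max:
            raise ValueError(
                f"age_min ({self.age_min}) exceeds age_max ({self.age_max})"
            )


def hedges_correction(df: int) -> float:
    """Exact Hedges small-sample correction factor J(df).

    J = Gamma(df/2) / (sqrt(df/2) * Gamma((df-1)/2)); approximately
    1 - 3/(4*df - 1).
    """
    return math.exp(
        math.lgamma(df / 2.0) - 0.5 * math.log(df / 2.0) - math.lgamma((df - 1) / 2.0)
    )


def sampling_variance(d: float, n: int) -> float:
    """Large-sample variance of a paired-samples standardized mean difference."""
    return 1.0 / n + d * d / (2.0 * n)


def paired_effect(
    sample: PairedMeasurements,
    dataset_id: str = "",
    measure_id: str = "",
    hedges: bool = False,
) -> EffectRecord:
    """Paired t-test and Cohen's d_z for one dataset's left/right measurements.

    Raises
    ------
    DegenerateSampleError
        If all paired differences are identical (zero SD), in which case the
        t statistic is undefined.
    """
    return paired_effect_from_differences(
        sample.differences, dataset_id=dataset_id, measure_id=measure_id, hedges=hedges
    )


def paired_effect_from_differences(
    differences: np.ndarray,
    dataset_id: str = "",
    measure_id: str = "",
    hedges: bool = False,
) -> EffectRecord:
    """As :func:`paired_effect`, but starting from the vector of L-R differences."""
    diff = np.asarray(differences, dtype=float)
    if diff.ndim != 1 or diff.size < 2:
        raise ValueError("differences must be a vector of length >= 2")
    if not np.isfinite(diff).all():
        raise ValueError("differences must be finite")
    n = int(diff.size)
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0.0:
        raise DegenerateSampleError(
            f"dataset={dataset_id!r} measure={measure_id!r}: all {n} paired "
            "differences are identical (SD of differences is zero); the paired "
            "t statistic is undefined"
        )
    t = mean_diff / (sd_diff / math.sqrt(n))
    d = mean_diff / sd_diff
    if hedges:
        d *= hedges_correction(n - 1)
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return EffectRecord(
        dataset_id=dataset_id,
        measure_id=measure_id,
        n=n,
        t=float(t),
        d=float(d),
        var_d=sampling_variance(d, n),
        p=p,
        df=n - 1,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
    )


def effect_from_t(
    t: float,
    n: int,
    dataset_id: str = "",
    measure_id: str = "",
    hedges: bool = False,
) -> EffectRecord:
    """Reconstruct an effect record when only t and n are available.

    Deposited summary tables often carry just the per-dataset t statistic and
    sample size; d, its variance and the two-sided p-value follow from those.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    d = t / math.sqrt(n)
    if hedges:
        d *= hedges_correction(n - 1)
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return EffectRecord(
        dataset_id=dataset_id,
        measure_id=measure_id,
        n=int(n),
        t=float(t),
        d=float(d),
        var_d=sampling_variance(d, n),
        p=p,
        df=int(n) - 1,
    )
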