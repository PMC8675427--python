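"""Leave-one-out reproduction criterion and reproducibility rates.

A dataset *reproduces* an effect by comparison with the meta-analysis of all
other datasets (leave-one-out, to avoid sample overlap):

* pooled effect significant (p <= alpha_meta): the single dataset must show
  the same left-right direction AND be nominally significant
  (p <= alpha_single);
* pooled effect nonsignificant: the single dataset must also be
  nonsignificant (p > alpha_single).

The reproducibility rate of an effect is the proportion of evaluated
datasets that reproduce it.  Stratified variants restrict the datasets by
minimum sample size, group effects by pooled |d|, and rerun the pipeline
within metadata-defined subgroups.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from asymrepro.effects import EffectRecord
from asymrepro.errors import DegenerateSampleError
from asymrepro.meta import (
    MetaResult,
    loo_meta,
    loo_meta_arrays_dl,
    meta_analyze_arrays,
    random_effects_meta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_BINS",
    "ReproCriterion",
    "ReproResult",
    "SubgroupComparison",
    "is_reproduced",
    "reproducibility_rate",
    "reproducibility_by_measure",
    "summarize_rates",
    "stratify_by_min_n",
    "bin_by_effect_size",
    "compare_subgroups",
    "subgroup_meta_reproducibility",
    "group_by_measure",
]

DEFAULT_THRESHOLDS = (15, 50, 100, 150, 200, 300, 400, 500)
DEFAULT_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.8)


@dataclass(frozen=True)
class ReproCriterion:
    """Parameters of the reproduction criterion.

    ``alpha_meta`` classifies the pooled (leave-one-out) effect as
    significant or not; ``alpha_single`` is the fixed nominal level for the
    single dataset; ``min_n`` restricts which datasets enter the rate
    denominator (the leave-one-out pools always use all other datasets).
    The Bonferroni variant divides only ``alpha_meta`` by the number of
    effects, never ``alpha_single``.
    """

    alpha_meta: float = 0.05
    alpha_single: float = 0.05
    n_effects_for_correction: int = 70
    min_n: int = 15

    def __post_init__(self):
        if not 0.0 < self.alpha_meta < 1.0:
            raise ValueError(f"alpha_meta must lie in (0,1), got {self.alpha_meta}")
        if not 0.0 < self.alpha_single < 1.0:
            raise ValueError(f"alpha_single must lie in (0,1), got {self.alpha_single}")

    def bonferroni(self) -> "ReproCriterion":
        """Variant with alpha_meta = alpha_meta / m (m effects tested)."""
        return replace(self, alpha_meta=self.alpha_meta / self.n_effects_for_correction)


@dataclass(frozen=True)
class ReproResult:
    """Per-measure reproducibility rate and per-dataset reproduction flags."""

    measure_id: str
    rate: float
    n_eval: int
    flags: Mapping[str, bool]
    meta_branch: Mapping[str, str]  # dataset_id -> {"significant", "nonsignificant"}

    def __post_init__(self):
        if self.n_eval != len(self.flags):
            raise ValueError("n_eval must equal the number of evaluated datasets")
        expected = sum(self.flags.values()) / len(self.flags) if self.flags else float("nan")
        if self.flags and abs(self.rate - expected) > 1e-12:
            raise ValueError("rate must equal the mean of the flags exactly")


@dataclass(frozen=True)
class SubgroupComparison:
    """t-test and Mann-Whitney comparison of two groups of rates."""

    t: float
    df: float
    p_t: float
    u: float
    p_u: float
    paired: bool
    wilcoxon_w: float | None = None
    p_wilcoxon: float | None = None


def is_reproduced(
    meta: MetaResult, single: EffectRecord, crit: ReproCriterion
) -> bool:
    """Apply the reproduction criterion to one dataset against its LOO pool."""
    if meta.excluded_dataset is not None and meta.excluded_dataset != single.dataset_id:
        raise ValueError(
            f"meta excludes {meta.excluded_dataset!r} but single dataset is "
            f"{single.dataset_id!r}"
        )
    if meta.p <= crit.alpha_meta:
        if single.d == 0.0:
            logger.debug(
                "dataset=%s measure=%s: d is exactly 0 against a significant "
                "pooled effect; counted as not reproduced",
                single.dataset_id,
                single.measure_id,
            )
            return False
        return (
            math.copysign(1.0, single.d) == math.copysign(1.0, meta.pooled_d)
            and single.p <= crit.alpha_single
        )
    return single.p > crit.alpha_single


def _loo_stats(
    recs: Sequence[EffectRecord], method: str
) -> tuple[np.ndarray, np.ndarray]:
    """(pooled_d, pooled_p) of the leave-one-out pools, aligned to recs."""
    if method == "DL":
        d = np.array([r.d for r in recs])
        v = np.array([r.var_d for r in recs])
        pooled, _, p, _ = loo_meta_arrays_dl(d, v)
        return pooled, p
    results = loo_meta(recs, method=method)
    return (
        np.array([m.pooled_d for m in results]),
        np.array([m.p for m in results]),
    )


def reproducibility_rate(
    records: Sequence[EffectRecord],
    crit: ReproCriterion = ReproCriterion(),
    method: str = "REML",
) -> ReproResult:
    """Leave-one-out reproducibility rate of one measure across datasets.

    Every dataset is compared against the meta-analysis of all the others
    (the pools are never filtered); only datasets with ``n >= crit.min_n``
    enter the rate denominator.
    """
    recs = list(records)
    if len(recs) < 3:
        raise ValueError(f"need at least 3 datasets, got {len(recs)}")
    measure_id = recs[0].measure_id
    pooled_d, pooled_p = _loo_stats(recs, method)
    flags: dict[str, bool] = {}
    branches: dict[str, str] = {}
    for i, rec in enumerate(recs):
        significant = pooled_p[i] <= crit.alpha_meta
        branches[rec.dataset_id] = "significant" if significant else "nonsignificant"
        if rec.n < crit.min_n:
            continue
        if significant:
            ok = (
                rec.d != 0.0
                and math.copysign(1.0, rec.d) == math.copysign(1.0, pooled_d[i])
                and rec.p <= crit.alpha_single
            )
            if rec.d == 0.0:
                logger.debug(
                    "dataset=%s measure=%s: d=0 against significant pool",
                    rec.dataset_id,
                    measure_id,
                )
        else:
            ok = rec.p > crit.alpha_single
        flags[rec.dataset_id] = bool(ok)
    if not flags:
        raise ValueError(
            f"measure {measure_id!r}: no dataset passes min_n={crit.min_n}"
        )
    rate = sum(flags.values()) / len(flags)
    return ReproResult(
        measure_id=measure_id,
        rate=rate,
        n_eval=len(flags),
        flags=flags,
        meta_branch=branches,
    )


def group_by_measure(
    records: Iterable[EffectRecord],
) -> dict[str, list[EffectRecord]]:
    """Group effect records by measure, preserving dataset order."""
    out: dict[str, list[EffectRecord]] = {}
    for rec in records:
        out.setdefault(rec.measure_id, []).append(rec)
    return out


def reproducibility_by_measure(
    records: Iterable[EffectRecord],
    crit: ReproCriterion = ReproCriterion(),
    method: str = "REML",
) -> dict[str, ReproResult]:
    """Reproducibility rate for every measure in a multi-measure table."""
    return {
        measure: reproducibility_rate(recs, crit=crit, method=method)
        for measure, recs in group_by_measure(records).items()
    }


def summarize_rates(
    repro: Sequence[ReproResult],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean/SD/min/max of reproducibility rates, overall and per group.

    ``grouping`` maps measure_id to a group label (e.g. thickness vs area, or
    regional vs whole-hemisphere).  SD uses denominator n-1 and is reported
    as NaN for singleton groups.
    """
    if not repro:
        raise ValueError("no reproducibility results supplied")

    def _row(label: str, rates: np.ndarray) -> dict:
        return {
            "group": label,
            "n_effects": rates.size,
            "mean": float(rates.mean()),
            "sd": float(rates.std(ddof=1)) if rates.size > 1 else float("nan"),
            "min": float(rates.min()),
            "max": float(rates.max()),
        }

    all_rates = np.array([r.rate for r in repro])
    rows = [_row("overall", all_rates)]
    if grouping is not None:
        groups: dict[str, list[float]] = {}
        for r in repro:
            groups.setdefault(grouping.get(r.measure_id, "ungrouped"), []).append(r.rate)
        for label in sorted(groups):
            rows.append(_row(label, np.array(groups[label])))
    return pd.DataFrame(rows)


def stratify_by_min_n(
    records: Iterable[EffectRecord],
    crit: ReproCriterion = ReproCriterion(),
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    method: str = "REML",
) -> pd.DataFrame:
    """Per-effect reproducibility at increasing minimum-sample-size thresholds.

    For each threshold both the leave-one-out pools and the rate denominator
    are restricted to datasets with ``n >= threshold`` (a subgroup
    re-analysis).  Thresholds leaving fewer than 3 qualifying datasets are
    flagged unavailable (rate NaN).
    """
    thresholds = list(thresholds)
    if any(b > a for b, a in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be ascending, got {thresholds}")
    by_measure = group_by_measure(records)
    rows = []
    for threshold in thresholds:
        for measure, recs in by_measure.items():
            sub = [r for r in recs if r.n >= threshold]
            n_datasets = len(sub)
            if n_datasets < 3:
                rows.append(
                    {
                        "threshold": threshold,
                        "measure_id": measure,
                        "n_datasets": n_datasets,
                        "rate": float("nan"),
                        "n_eval": 0,
                        "available": False,
                    }
                )
                continue
            res = reproducibility_rate(
                sub, crit=replace(crit, min_n=threshold), method=method
            )
            rows.append(
                {
                    "threshold": threshold,
                    "measure_id": measure,
                    "n_datasets": n_datasets,
                    "rate": res.rate,
                    "n_eval": res.n_eval,
                    "available": True,
                }
            )
    return pd.DataFrame(rows)


def bin_by_effect_size(
    meta_results: Sequence[MetaResult],
    bins: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Assign measures to |pooled d| bins (half-open [lo, hi), full-pool meta).

    Binning uses the meta-analytic effect over *all* datasets, not the
    leave-one-out pools.  A |pooled d| outside every bin lands in an
    "overflow" bin with a warning.
    """
    edges = list(bins)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly ascending, got {edges}")
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges, edges[1:])]
    rows = []
    for m in meta_results:
        mag = abs(m.pooled_d)
        idx = None
        for j, (lo, hi) in enumerate(zip(edges, edges[1:])):
            if lo <= mag < hi:
                idx = j
                break
        if idx is None:
            warnings.warn(
                f"measure {m.measure_id!r}: |pooled d| = {mag:.4g} outside all "
                f"bins {edges}; assigned to overflow bin",
                stacklevel=2,
            )
            label = "overflow"
        else:
            label = labels[idx]
        rows.append(
            {"measure_id": m.measure_id, "pooled_d": m.pooled_d, "abs_d": mag, "bin": label}
        )
    return pd.DataFrame(rows)


def compare_subgroups(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    paired: bool = False,
) -> SubgroupComparison:
    """Compare two groups of per-effect rates by t-test and Mann-Whitney U.

    Paired mode (matched regions) uses the paired t-test (df = k-1) and also
    reports the Wilcoxon signed-rank statistic; the Mann-Whitney U treating
    the two groups as independent samples is reported in both modes.
    Unpaired mode uses the Welch t-test.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u_res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison needs equal-length groups")
        diff = a - b
        if diff.std(ddof=1) == 0.0:
            raise DegenerateSampleError(
                "paired comparison: zero variance of differences"
            )
        t_res = stats.ttest_rel(a, b)
        w_res = stats.wilcoxon(a, b)
        return SubgroupComparison(
            t=float(t_res.statistic),
            df=float(a.size - 1),
            p_t=float(t_res.pvalue),
            u=float(u_res.statistic),
            p_u=float(u_res.pvalue),
            paired=True,
            wilcoxon_w=float(w_res.statistic),
            p_wilcoxon=float(w_res.pvalue),
        )
    t_res = stats.ttest_ind(a, b, equal_var=False)
    return SubgroupComparison(
        t=float(t_res.statistic),
        df=float(t_res.df),
        p_t=float(t_res.pvalue),
        u=float(u_res.statistic),
        p_u=float(u_res.pvalue),
        paired=False,
    )


def rates_within_datasets(
    repro: Mapping[str, ReproResult], dataset_ids: Iterable[str]
) -> dict[str, float]:
    """Per-measure reproduction rates restricted to a subset of datasets.

    Reuses the main-analysis flags (leave-one-out against all other
    datasets); only the averaging is restricted, mirroring comparisons of
    rates between dataset subgroups.  Measures with no evaluated dataset in
    the subset get NaN.
    """
    keep = set(dataset_ids)
    out = {}
    for measure, res in repro.items():
        vals = [flag for ds, flag in res.flags.items() if ds in keep]
        out[measure] = sum(vals) / len(vals) if vals else float("nan")
    return out


def subgroup_meta_reproducibility(
    records: Iterable[EffectRecord],
    metadata: pd.DataFrame,
    predicate: Callable[[pd.Series], bool],
    crit: ReproCriterion = ReproCriterion(),
    method: str = "REML",
) -> dict[str, ReproResult]:
    """Full LOO reproducibility pipeline restricted to a metadata subgroup.

    ``metadata`` must carry one row per dataset with a ``dataset_id`` column;
    ``predicate`` selects rows.  Subgroup-specific pooled ("true") effects are
    re-estimated within the subgroup.
    """
    keep = {
        row["dataset_id"]
        for _, row in metadata.iterrows()
        if predicate(row)
    }
    sub = [r for r in records if r.dataset_id in keep]
    n_datasets = len({r.dataset_id for r in sub})
    if n_datasets < 3:
        raise ValueError(
            f"subgroup has only {n_datasets} datasets; need at least 3"
        )
    return reproducibility_by_measure(sub, crit=crit, method=method)
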