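"""Inverse-variance-weighted random-effects meta-analysis.

Per-dataset effects d_i with sampling variances v_i are pooled under the
normal-normal model d_i ~ N(mu, v_i + tau^2).  The between-dataset variance
tau^2 is estimated either by the closed-form DerSimonian-Laird moment
estimator (``DL``) or by restricted maximum likelihood (``REML``, the
default); ``FE`` fixes tau^2 = 0.  Pooled inference uses the standard normal
reference: z = pooled_d / se, p two-sided.

The leave-one-out pooling (:func:`loo_meta`) refits tau^2 within every
reduced pool, so each result is exactly the meta-analysis a researcher would
have run on the remaining datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from asymrepro.effects import EffectRecord
from asymrepro.errors import ConvergenceError

__all__ = [
    "MetaResult",
    "tau2_dl",
    "tau2_reml",
    "random_effects_meta",
    "loo_meta",
    "METHODS",
]

METHODS = ("DL", "REML", "FE")


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate for one measure."""

    measure_id: str
    k: int
    pooled_d: float
    se: float
    z: float
    p: float
    tau2: float
    Q: float
    method: str
    excluded_dataset: str | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.method == "FE" and self.tau2 != 0.0:
            raise ValueError("fixed-effect result must have tau2 = 0")


def _check_dv(d: np.ndarray, v: np.ndarray, min_k: int = 2) -> None:
    if d.shape != v.shape or d.ndim != 1:
        raise ValueError("d and v must be equal-length vectors")
    if d.size < min_k:
        raise ValueError(f"need at least {min_k} studies, got {d.size}")
    if not (v > 0).all():
        raise ValueError("all sampling variances must be positive")
    if not (np.isfinite(d).all() and np.isfinite(v).all()):
        raise ValueError("d and v must be finite")


def _q_statistic(d: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    dbar = float(np.sum(w * d) / np.sum(w))
    return float(np.sum(w * (d - dbar) ** 2))


def tau2_dl(d: Sequence[float], v: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    With w_i = 1/v_i, Q = sum w_i (d_i - dbar)^2 and
    C = sum w_i - sum w_i^2 / sum w_i, the estimate is
    max(0, (Q - (k-1)) / C).
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_dv(d, v)
    w = 1.0 / v
    sw = float(np.sum(w))
    q = _q_statistic(d, v)
    c = sw - float(np.sum(w * w)) / sw
    return max(0.0, (q - (d.size - 1)) / c)


def _reml_score(tau2: float, d: np.ndarray, v: np.ndarray) -> float:
    """Derivative of the restricted log-likelihood with respect to tau^2."""
    w = 1.0 / (v + tau2)
    sw = np.sum(w)
    mu = np.sum(w * d) / sw
    return 0.5 * float(-sw + np.sum(w * w) / sw + np.sum(w * w * (d - mu) ** 2))


def tau2_reml(
    d: Sequence[float],
    v: Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """REML estimate of the between-study variance.

    Maximizes the restricted log-likelihood of the normal-normal model by
    solving the score equation with bounded one-dimensional root finding;
    returns 0 when the score at the boundary is non-positive (the estimate
    is truncated at zero).

    Raises
    ------
    ConvergenceError
        If no sign change is bracketed or the root finder does not converge
        within ``max_iter``; the exception carries the last iterate.
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_dv(d, v)
    if _reml_score(0.0, d, v) <= 0.0:
        return 0.0
    # Expand an upper bracket; the score is eventually negative since the
    # profiled likelihood decays for tau^2 far above the dispersion of d.
    hi = max(float(np.var(d, ddof=1)), float(np.mean(v)), 1e-8)
    for _ in range(200):
        if _reml_score(hi, d, v) < 0.0:
            break
        hi *= 2.0
    else:
        raise ConvergenceError(
            "REML: could not bracket the score root", last_value=hi
        )
    try:
        root, info = optimize.brentq(
            _reml_score,
            0.0,
            hi,
            args=(d, v),
            xtol=tol,
            maxiter=max_iter,
            full_output=True,
        )
    except RuntimeError as exc:  # brentq raises on maxiter exhaustion
        raise ConvergenceError(f"REML did not converge: {exc}", last_value=hi) from exc
    if not info.converged:
        raise ConvergenceError(
            "REML did not converge", last_value=float(info.root)
        )
    return float(root)


def _estimate_tau2(d: np.ndarray, v: np.ndarray, method: str) -> float:
    if method == "FE":
        return 0.0
    if method == "DL":
        return tau2_dl(d, v)
    if method == "REML":
        return tau2_reml(d, v)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _records_to_arrays(
    records: Iterable[EffectRecord],
) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    recs = list(records)
    if not recs:
        raise ValueError("no effect records supplied")
    d = np.array([r.d for r in recs], dtype=float)
    v = np.array([r.var_d for r in recs], dtype=float)
    ids = [r.dataset_id for r in recs]
    measures = {r.measure_id for r in recs}
    if len(measures) > 1:
        raise ValueError(f"records mix measures: {sorted(measures)}")
    return d, v, ids, recs[0].measure_id


def pool_fixed_tau2(
    d: np.ndarray,
    v: np.ndarray,
    tau2: float,
    q: float,
    method: str,
    measure_id: str = "",
    excluded_dataset: str | None = None,
) -> MetaResult:
    """Pool with weights 1/(v_i + tau2) for an already-estimated tau2."""
    w = 1.0 / (v + tau2)
    sw = float(np.sum(w))
    pooled = float(np.sum(w * d) / sw)
    se = sw ** -0.5
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        measure_id=measure_id,
        k=int(d.size),
        pooled_d=pooled,
        se=se,
        z=z,
        p=p,
        tau2=float(tau2),
        Q=float(q),
        method=method,
        excluded_dataset=excluded_dataset,
    )


def meta_analyze_arrays(
    d: Sequence[float],
    v: Sequence[float],
    method: str = "REML",
    measure_id: str = "",
    excluded_dataset: str | None = None,
) -> MetaResult:
    """Array-level random-effects meta-analysis (no EffectRecord wrapping)."""
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_dv(d, v, min_k=1)
    if d.size == 1:
        # A single study is its own pool: tau^2 undefined, reported as 0.
        return pool_fixed_tau2(
            d, v, 0.0, 0.0, method, measure_id=measure_id,
            excluded_dataset=excluded_dataset,
        )
    tau2 = _estimate_tau2(d, v, method)
    q = _q_statistic(d, v)
    return pool_fixed_tau2(
        d, v, tau2, q, method, measure_id=measure_id,
        excluded_dataset=excluded_dataset,
    )


def random_effects_meta(
    records: Iterable[EffectRecord], method: str = "REML"
) -> MetaResult:
    """Pool one measure's per-dataset effects across datasets."""
    d, v, _, measure_id = _records_to_arrays(records)
    return meta_analyze_arrays(d, v, method=method, measure_id=measure_id)


def loo_meta(
    records: Sequence[EffectRecord], method: str = "REML"
) -> list[MetaResult]:
    """Leave-one-out meta-analyses, one per excluded dataset, in input order.

    tau^2 is re-estimated within every reduced pool.
    """
    recs = list(records)
    if len(recs) < 3:
        raise ValueError(
            f"leave-one-out pooling needs at least 3 datasets, got {len(recs)}"
        )
    d, v, ids, measure_id = _records_to_arrays(recs)
    results = []
    for i, excluded in enumerate(ids):
        mask = np.ones(d.size, dtype=bool)
        mask[i] = False
        results.append(
            meta_analyze_arrays(
                d[mask], v[mask], method=method, measure_id=measure_id,
                excluded_dataset=excluded,
            )
        )
    return results


def loo_meta_arrays_dl(
    d: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized leave-one-out DL pooling.

    Returns (pooled_d, se, p, tau2), each of length k, where entry i pools all
    studies except i.  Used by simulation studies where thousands of LOO fits
    are needed; exactly equivalent to looping :func:`meta_analyze_arrays`
    with method="DL".
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_dv(d, v, min_k=3)
    k = d.size
    w = 1.0 / v
    s1 = w.sum() - w                      # sum of weights without i
    sd = (w * d).sum() - w * d
    sdd = (w * d * d).sum() - w * d * d
    s2 = (w * w).sum() - w * w
    q = sdd - sd * sd / s1
    c = s1 - s2 / s1
    tau2 = np.maximum(0.0, (q - (k - 2)) / c)
    ws = 1.0 / (v[None, :] + tau2[:, None])   # row i: RE weights at tau2_i
    np.fill_diagonal(ws, 0.0)
    sws = ws.sum(axis=1)
    pooled = (ws * d[None, :]).sum(axis=1) / sws
    se = sws ** -0.5
    p = 2.0 * stats.norm.sf(np.abs(pooled / se))
    return pooled, se, p, tau2
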