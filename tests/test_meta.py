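"""Random-effects meta-analysis: hand-checked fixtures, independent oracles.

Frozen cross-check values were computed with the metafor R package (REML via
Fisher scoring, convergence threshold ~1e-5) and with an independent
grid-search maximizer of the restricted likelihood.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asymrepro.errors import ConvergenceError
from asymrepro.meta import (
    loo_meta,
    loo_meta_arrays_dl,
    meta_analyze_arrays,
    random_effects_meta,
    tau2_dl,
    tau2_reml,
)
from tests.conftest import make_record

FIX_D = [0.2, 0.5, 0.8]
FIX_V = [0.04, 0.04, 0.04]
# 5-study fixture with unequal variances; metafor reference values.
FIX2_D = [0.1, 0.25, 0.4, -0.05, 0.6]
FIX2_V = [0.02, 0.01, 0.05, 0.03, 0.08]
FIX2_REML = dict(tau2=0.0022871432, b=0.2027874172, se=0.0728348137, z=2.7842100087)
FIX2_DL = dict(tau2=0.0108611825, b=0.2054948705, se=0.0869569079)


def _grid_reml(d, v, lo=0.0, hi=0.05, step=1e-6):
    """Independent restricted-likelihood grid maximizer (test-side oracle)."""
    d = np.asarray(d)
    v = np.asarray(v)
    grid = np.arange(lo, hi + step, step)
    best, best_ll = lo, -np.inf
    for t2 in grid:
        w = 1.0 / (v + t2)
        mu = (w * d).sum() / w.sum()
        ll = -0.5 * (np.log(v + t2).sum() + np.log(w.sum()) + (w * (d - mu) ** 2).sum())
        if ll > best_ll:
            best, best_ll = t2, ll
    return best


class TestTau2DL:
    def test_homogeneous_is_zero(self):
        assert tau2_dl([0.5, 0.5, 0.5], [0.04] * 3) == 0.0

    def test_hand_computed_fixture(self):
        """w=25 each, dbar=0.5, Q=4.5, C=50 -> tau2 = (4.5-2)/50 = 0.05."""
        assert tau2_dl(FIX_D, FIX_V) == pytest.approx(0.05, abs=1e-14)

    def test_truncation_at_zero(self):
        # Q = 0.005 < k-1 = 1, so the moment estimate is truncated.
        assert tau2_dl([0.5, 0.6], [1.0, 1.0]) == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            tau2_dl([0.5], [0.04])

    def test_matches_metafor_on_unequal_variances(self):
        assert tau2_dl(FIX2_D, FIX2_V) == pytest.approx(FIX2_DL["tau2"], abs=1e-9)


class TestTau2REML:
    def test_homogeneous_is_zero(self):
        assert tau2_reml([0.5, 0.5, 0.5], [0.04] * 3) == 0.0

    def test_equal_variance_fixture_grid_oracle(self):
        # With equal v, REML has the closed form var(d, ddof=1) - v = 0.05;
        # the grid oracle and the root finder must both land there.
        est = tau2_reml(FIX_D, FIX_V)
        assert est == pytest.approx(0.05, abs=1e-8)
        assert est == pytest.approx(_grid_reml(FIX_D, FIX_V, hi=0.2, step=1e-5), abs=2e-5)

    def test_matches_metafor_and_grid_on_unequal_variances(self):
        est = tau2_reml(FIX2_D, FIX2_V)
        assert est == pytest.approx(FIX2_REML["tau2"], abs=1e-5)
        assert est == pytest.approx(_grid_reml(FIX2_D, FIX2_V, hi=0.02), abs=2e-6)

    def test_recovery_at_moderate_k(self, rng):
        """Mean REML estimate over replicates recovers the generating tau2."""
        tau2_true, k = 0.04, 60
        v = 1.0 / rng.integers(30, 300, size=k)
        ests = []
        for _ in range(100):
            d = rng.normal(0.3, np.sqrt(v + tau2_true))
            ests.append(tau2_reml(d, v))
        assert np.mean(ests) == pytest.approx(tau2_true, abs=0.01)

    def test_nonconvergence_reports_last_iterate(self):
        with pytest.raises(ConvergenceError) as err:
            tau2_reml(FIX2_D, FIX2_V, tol=1e-12, max_iter=2)
        assert err.value.last_value is not None


class TestRandomEffectsMeta:
    def test_single_study_identity(self):
        res = random_effects_meta([make_record(d=0.3, var_d=0.01, p=0.01)])
        assert res.pooled_d == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)
        assert res.z == pytest.approx(3.0)
        assert res.tau2 == 0.0
        assert res.k == 1

    def test_hand_computed_dl_pooling(self):
        """tau2=0.05 -> w*=1/0.09 each -> pooled 0.5, se 0.1732, z 2.887."""
        res = meta_analyze_arrays(FIX_D, FIX_V, method="DL")
        assert res.tau2 == pytest.approx(0.05, abs=1e-14)
        assert res.pooled_d == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(0.17320508075688773, abs=1e-12)
        assert res.z == pytest.approx(2.8867513459481295, abs=1e-10)

    def test_fe_equals_dl_when_tau2_zero(self):
        d, v = [0.5, 0.5, 0.5], [0.04, 0.02, 0.08]
        fe = meta_analyze_arrays(d, v, method="FE")
        dl = meta_analyze_arrays(d, v, method="DL")
        assert fe.pooled_d == dl.pooled_d
        assert fe.se == dl.se
        assert fe.tau2 == dl.tau2 == 0.0

    def test_reml_pooling_matches_metafor(self):
        res = meta_analyze_arrays(FIX2_D, FIX2_V, method="REML")
        assert res.pooled_d == pytest.approx(FIX2_REML["b"], abs=2e-5)
        assert res.se == pytest.approx(FIX2_REML["se"], abs=2e-5)
        assert res.z == pytest.approx(FIX2_REML["z"], abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            random_effects_meta([])

    @given(
        d=st.lists(st.floats(-2, 2), min_size=2, max_size=5),
        v=st.lists(st.floats(0.001, 1), min_size=2, max_size=5),
        method=st.sampled_from(["DL", "REML", "FE"]),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_structural_invariants(self, d, v, method):
        """Convexity, z/p consistency, order invariance, precision dominance."""
        k = min(len(d), len(v))
        d, v = np.array(d[:k]), np.array(v[:k])
        res = meta_analyze_arrays(d, v, method=method)
        assert d.min() - 1e-12 <= res.pooled_d <= d.max() + 1e-12
        assert res.z == pytest.approx(res.pooled_d / res.se, abs=1e-12)
        assert res.se <= np.sqrt(v + res.tau2).min() + 1e-12
        perm = np.argsort(d)
        res_perm = meta_analyze_arrays(d[perm], v[perm], method=method)
        assert res_perm.pooled_d == pytest.approx(res.pooled_d, abs=1e-10)
        assert res_perm.se == pytest.approx(res.se, abs=1e-10)

    def test_direct_formula_oracle_small_k(self, rng):
        """pooled_d and se match an independent direct evaluation to 1e-10."""
        for k in (2, 3, 5):
            d = rng.normal(0.2, 0.3, size=k)
            v = rng.uniform(0.01, 0.2, size=k)
            res = meta_analyze_arrays(d, v, method="DL")
            w = 1.0 / (v + res.tau2)
            assert res.pooled_d == pytest.approx(float((w * d).sum() / w.sum()), abs=1e-10)
            assert res.se == pytest.approx(float(w.sum() ** -0.5), abs=1e-10)
            assert (w / w.sum()).sum() == pytest.approx(1.0, abs=1e-12)


class TestLeaveOneOut:
    def test_symmetric_pools_hand_checkable(self):
        recs = [make_record(dataset_id=f"d{i}", d=0.5, var_d=0.04) for i in range(3)]
        results = loo_meta(recs, method="DL")
        assert [r.excluded_dataset for r in results] == ["d0", "d1", "d2"]
        for r in results:
            assert r.k == 2
            assert r.pooled_d == pytest.approx(0.5)
            assert r.tau2 == 0.0
            assert r.se == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_cardinality(self, rng):
        recs = [
            make_record(dataset_id=f"d{i}", d=float(rng.normal(0.3, 0.1)), var_d=0.02)
            for i in range(20)
        ]
        results = loo_meta(recs)
        assert len(results) == 20
        assert all(r.k == 19 for r in results)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            loo_meta([make_record(dataset_id="a"), make_record(dataset_id="b")])

    def test_excluding_outlier_minimizes_tau2_brute_force(self):
        """All-subsets oracle: dropping the outlier gives the smallest tau2."""
        d = [0.50, 0.52, 0.48, 1.60]
        v = [0.02, 0.02, 0.02, 0.02]
        recs = [
            make_record(dataset_id=f"d{i}", d=di, var_d=vi)
            for i, (di, vi) in enumerate(zip(d, v))
        ]
        results = loo_meta(recs, method="DL")
        tau2_by_excluded = {r.excluded_dataset: r.tau2 for r in results}
        # brute force over all leave-one-out index subsets
        brute = {}
        for keep in itertools.combinations(range(4), 3):
            (excluded,) = set(range(4)) - set(keep)
            brute[f"d{excluded}"] = tau2_dl([d[i] for i in keep], [v[i] for i in keep])
        assert tau2_by_excluded == pytest.approx(brute)
        assert min(tau2_by_excluded, key=tau2_by_excluded.get) == "d3"

    def test_vectorized_dl_equals_looped(self, rng):
        d = rng.normal(0.3, 0.25, size=30)
        v = 1.0 / rng.integers(15, 500, size=30)
        pooled, se, p, tau2 = loo_meta_arrays_dl(d, v)
        recs = [
            make_record(dataset_id=f"d{i}", d=float(di), var_d=float(vi))
            for i, (di, vi) in enumerate(zip(d, v))
        ]
        looped = loo_meta(recs, method="DL")
        np.testing.assert_allclose(pooled, [r.pooled_d for r in looped], atol=1e-12)
        np.testing.assert_allclose(se, [r.se for r in looped], atol=1e-12)
        np.testing.assert_allclose(p, [r.p for r in looped], atol=1e-12)
        np.testing.assert_allclose(tau2, [r.tau2 for r in looped], atol=1e-12)


def test_dl_and_reml_agree_in_probability_on_homogeneous_data(rng):
    """Both tau2 estimators concentrate at 0 as k grows when tau = 0."""
    k = 150
    n = rng.integers(50, 500, size=k)
    v = 1.0 / n
    d = rng.normal(0.3, np.sqrt(v))
    assert tau2_dl(d, v) < 0.005
    assert tau2_reml(d, v) < 0.005
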