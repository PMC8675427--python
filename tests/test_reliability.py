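"""ICC from two-way mean squares, Spearman correlates, regional profiles."""

import numpy as np
import pytest

from asymrepro.reliability import RegionProfile, icc, regional_correlates, spearman
from asymrepro.synthetic import simulate_test_retest

TEST6 = np.array([10.0, 12.0, 14.0, 11.0, 13.0, 15.0])
RETEST6 = np.array([11.2, 12.9, 14.6, 11.9, 13.4, 16.1])
# frozen mean-squares hand computation: MSR=6.6655, MSC=2.1675, MSE=0.0455
ICC_A1 = 0.8923837339923615
ICC_C1 = 0.986440172850544


class TestICC:
    def test_identical_sessions_give_one(self):
        rec = icc(TEST6, TEST6)
        assert rec.icc == pytest.approx(1.0, abs=1e-12)

    def test_hand_fixture_absolute_and_consistency(self):
        assert icc(TEST6, RETEST6, model="absolute").icc == pytest.approx(ICC_A1, abs=1e-10)
        assert icc(TEST6, RETEST6, model="consistency").icc == pytest.approx(ICC_C1, abs=1e-10)

    def test_permuted_retest_near_zero(self, rng):
        x = rng.normal(0, 1, size=2000)
        rec = icc(x, rng.permutation(x))
        # permutation oracle: the ICC of independent pairings is ~N(0, 1/n)
        assert abs(rec.icc) < 3 / np.sqrt(2000)

    def test_common_constant_invariance(self):
        base_a = icc(TEST6, RETEST6, model="absolute").icc
        base_c = icc(TEST6, RETEST6, model="consistency").icc
        shifted_a = icc(TEST6 + 7.0, RETEST6 + 7.0, model="absolute").icc
        shifted_c = icc(TEST6 + 7.0, RETEST6 + 7.0, model="consistency").icc
        assert shifted_a == pytest.approx(base_a, abs=1e-12)
        assert shifted_c == pytest.approx(base_c, abs=1e-12)

    def test_session_offset_hurts_absolute_not_consistency(self):
        offset = icc(TEST6, TEST6 + 2.0, model="absolute").icc
        consist = icc(TEST6, TEST6 + 2.0, model="consistency").icc
        assert consist == pytest.approx(1.0, abs=1e-12)
        assert offset < 0.9

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        frame = pd.DataFrame(
            {
                "subj": list(range(6)) * 2,
                "sess": ["a"] * 6 + ["b"] * 6,
                "y": np.concatenate([TEST6, RETEST6]),
            }
        )
        table = pg.intraclass_corr(frame, targets="subj", raters="sess", ratings="y")
        # pingouin's fixed row order: ICC1, ICC2 (=A,1), ICC3 (=C,1), then k-forms
        assert icc(TEST6, RETEST6, model="absolute").icc == pytest.approx(
            float(table.iloc[1]["ICC"]), abs=1e-9
        )
        assert icc(TEST6, RETEST6, model="consistency").icc == pytest.approx(
            float(table.iloc[2]["ICC"]), abs=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            icc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            icc([1.0], [2.0])


class TestSpearman:
    def test_monotone_transform_invariance(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.1])
        y = np.array([2.0, 4.0, 5.0, 6.0, 11.0])
        rho, _ = spearman(x, y)
        rho_t, _ = spearman(np.exp(x), y**3)
        assert rho == pytest.approx(1.0)
        assert rho_t == pytest.approx(rho, abs=1e-12)

    def test_reversal(self):
        rho, _ = spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_brute_force_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 7.0, 6.0, 9.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _profiles(rate_from_icc=None, rng=None):
    rng = rng or np.random.default_rng(3)
    profiles = []
    for i in range(34):
        icc_t = 0.5 + 0.4 * i / 33
        rate_t = rate_from_icc(icc_t) if rate_from_icc else float(rng.uniform(0.2, 1))
        profiles.append(
            RegionProfile(
                region=f"r{i}",
                mean_size=float(rng.uniform(500, 10000)),
                effect_size_thickness=float(rng.normal(0, 0.3)),
                effect_size_area=float(rng.normal(0, 0.5)),
                rate_thickness=rate_t,
                rate_area=float(rng.uniform(0.2, 1)),
                icc_thickness=icc_t,
                icc_area=float(rng.uniform(0.7, 0.99)),
            )
        )
    return profiles


class TestRegionalCorrelates:
    def test_planted_monotone_signal(self):
        table = regional_correlates(_profiles(rate_from_icc=lambda v: v**2))
        row = table.set_index(["x", "y"]).loc[("icc_thickness", "rate_thickness")]
        assert row["rho"] == pytest.approx(1.0)

    def test_shuffled_columns_mostly_nonsignificant(self, rng):
        hits, total = 0, 0
        for _ in range(100):
            table = regional_correlates(_profiles(rng=rng))
            row = table.set_index(["x", "y"]).loc[("icc_area", "rate_area")]
            hits += row["p"] <= 0.05
            total += 1
        assert hits / total <= 0.10

    def test_missing_field_names_region(self):
        bad = _profiles()
        import dataclasses

        bad[5] = dataclasses.replace(bad[5], icc_area=float("nan"))
        with pytest.raises(ValueError, match="r5"):
            regional_correlates(bad)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            regional_correlates(_profiles()[:2])


class TestSimulatedTestRetest:
    def test_recovers_target_icc(self):
        frame = simulate_test_retest({"ra": 0.9, "rb": 0.6}, n_subjects=3000, seed=4)
        for region, target in [("ra", 0.9), ("rb", 0.6)]:
            sub = frame[frame.region == region].pivot(
                index="subject", columns="session", values="value"
            )
            rec = icc(sub["test"], sub["retest"], model="consistency")
            assert rec.icc == pytest.approx(target, abs=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(Exception):
            simulate_test_retest({"ra": 1.5}, n_subjects=10, seed=1)
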