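"""Synthetic multiverse generator: determinism, calibration, mode equivalence."""

import numpy as np
import pytest

from asymrepro.effects import sampling_variance
from asymrepro.errors import ConfigurationError
from asymrepro.synthetic import (
    CovariateSpec,
    ExplicitSizes,
    LogUniformSizes,
    MeasureSpec,
    SimulationConfig,
    draw_sample_sizes,
    simulate_measure,
    simulate_multiverse,
    study_profile,
)

SPECS1 = (MeasureSpec("m1", 0.3),)


def config(**kw):
    base = dict(n_datasets=5, measure_specs=SPECS1, seed=42)
    base.update(kw)
    return SimulationConfig(**base)


class TestSampleSizes:
    def test_explicit_identity(self):
        cfg = config(n_datasets=3, size_law=ExplicitSizes((14, 72, 2326)))
        assert draw_sample_sizes(cfg) == [14, 72, 2326]

    def test_loguniform_bounds(self):
        cfg = config(n_datasets=99, size_law=LogUniformSizes(14, 2326))
        sizes = draw_sample_sizes(cfg)
        assert len(sizes) == 99
        assert all(14 <= s <= 2326 for s in sizes)

    def test_loguniform_median_matches_mc_oracle(self):
        """10^6-draw oracle put the median at ~180.4 (geometric-mean scale)."""
        cfg = config(n_datasets=10_000, size_law=LogUniformSizes(14, 2326))
        median = float(np.median(draw_sample_sizes(cfg)))
        assert 180.4 * 0.75 <= median <= 180.4 * 1.25

    def test_determinism(self):
        cfg = config(n_datasets=50)
        assert draw_sample_sizes(cfg) == draw_sample_sizes(cfg)

    def test_degenerate_law_rejected(self):
        with pytest.raises(ConfigurationError):
            LogUniformSizes(100, 100)
        with pytest.raises(ConfigurationError):
            ExplicitSizes((1, 50))

    def test_explicit_length_must_match(self):
        with pytest.raises(ConfigurationError):
            config(n_datasets=4, size_law=ExplicitSizes((10, 20)))


class TestSimulateMeasure:
    def test_huge_n_consistency(self):
        recs = simulate_measure(0.0, 0.0, [10**6], seed=1)
        assert abs(recs[0].d) < 0.01

    def test_mean_recovery_mc(self, rng):
        """At tau=0, mean observed d over many datasets recovers true d."""
        recs = simulate_measure(0.5, 0.0, [100] * 10_000, seed=rng)
        mean_d = np.mean([r.d for r in recs])
        assert mean_d == pytest.approx(0.5, abs=0.01)

    def test_variance_decomposition(self, rng):
        """Empirical SD of observed d ~ sqrt(tau^2 + mean sampling variance)."""
        true_d, tau, n, k = 0.3, 0.1, 200, 20_000
        recs = simulate_measure(true_d, tau, [n] * k, seed=rng)
        d = np.array([r.d for r in recs])
        expected_var = tau**2 + sampling_variance(true_d, n)
        assert d.std(ddof=1) == pytest.approx(np.sqrt(expected_var), rel=0.03)

    def test_individual_mode_consistent_with_paired_test(self, rng):
        recs = simulate_measure(0.4, 0.0, [30, 60], mode="individual", seed=rng)
        for rec in recs:
            # record fields satisfy the paired-test identities exactly
            assert rec.d == pytest.approx(rec.t / np.sqrt(rec.n), abs=1e-12)
            assert rec.mean_diff is not None and rec.sd_diff is not None
            assert rec.d == pytest.approx(rec.mean_diff / rec.sd_diff, abs=1e-12)

    def test_mode_equivalence_in_mean_and_variance(self):
        """Summary and individual modes agree at matched (d, tau=0, n)."""
        true_d, n, k = 0.3, 50, 4000
        rec_s = simulate_measure(true_d, 0.0, [n] * k, mode="summary", seed=7)
        rec_i = simulate_measure(true_d, 0.0, [n] * k, mode="individual", seed=8)
        ds = np.array([r.d for r in rec_s])
        di = np.array([r.d for r in rec_i])
        se_mean = np.sqrt(sampling_variance(true_d, n) / k)
        assert ds.mean() == pytest.approx(di.mean(), abs=4 * se_mean + 0.01)
        assert ds.std() == pytest.approx(di.std(), rel=0.10)

    def test_negative_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_measure(0.3, -0.1, [50], seed=1)


class TestSimulateMultiverse:
    def test_row_count_and_determinism(self):
        cfg = config(n_datasets=12, measure_specs=tuple(study_profile(6, tau=0.05)))
        a = simulate_multiverse(cfg)
        b = simulate_multiverse(cfg)
        assert len(a.effect_table) == 12 * 6
        assert a.effect_table == b.effect_table
        assert a.metadata_table.equals(b.metadata_table)
        assert a.truth_table.equals(b.truth_table)

    def test_minimal_case(self):
        cfg = config(n_datasets=1, size_law=ExplicitSizes((50,)))
        study = simulate_multiverse(cfg)
        assert len(study.effect_table) == 1

    def test_full_battery_shape(self):
        cfg = config(
            n_datasets=99, measure_specs=tuple(study_profile(70, tau=0.1))
        )
        study = simulate_multiverse(cfg)
        assert len(study.effect_table) == 6930
        assert study.metadata_table.shape[0] == 99
        assert set(study.metadata_table.columns) >= {
            "dataset_id", "n", "field_strength", "fs_version", "age_min", "age_max",
        }

    def test_covariate_levels(self):
        cfg = config(n_datasets=200)
        meta = simulate_multiverse(cfg).metadata_table
        assert set(meta.field_strength) <= {1.5, 3.0}
        assert set(meta.fs_version) <= {"5.0", "5.1", "5.3"}
        child = meta.age_max <= 18
        adult = meta.age_min >= 19
        assert child.any() and adult.any()
        assert (meta.age_min <= meta.age_max).all()

    def test_bad_covariate_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            CovariateSpec(field_strength={1.5: 0.7, 3.0: 0.7})


class TestStudyProfile:
    def test_emulates_published_distribution(self):
        specs = study_profile(70)
        mags = np.sort(np.abs([s.true_d for s in specs]))
        assert np.median(mags) == pytest.approx(0.30, abs=0.01)
        assert mags[-1] == pytest.approx(1.76, abs=1e-9)
        assert mags[0] == pytest.approx(0.0015, abs=1e-9)
        assert len({s.measure_id for s in specs}) == 70

    def test_area_stronger_than_thickness(self):
        specs = study_profile(70)
        thick = [abs(s.true_d) for s in specs if s.measure_id.endswith("_thickness")]
        area = [abs(s.true_d) for s in specs if s.measure_id.endswith("_area")]
        assert len(thick) == len(area) == 35
        assert np.mean(area) > np.mean(thick)

    def test_signs_alternate(self):
        signs = [np.sign(s.true_d) for s in study_profile(10)]
        assert set(signs) == {-1.0, 1.0}
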