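import numpy as np
import pytest
from scipy.stats import binom

from fcgraph.signal_cleaning import framewise_displacement
from fcgraph.synthetic_cohort import (
    ClinicalLink,
    CohortSpec,
    SubjectRecord,
    assign_clinical_covariates,
    benchmark_graph,
    generate_cohort,
    intra_module_mean_z,
    make_block_covariance,
    simulate_motion_trace,
    simulate_subject_timeseries,
)


class TestBlockCovariance:
    def test_two_blocks_direct_construction(self):
        cov, repaired = make_block_covariance((2, 2), 0.5, 0.0)
        expected = np.array([
            [1.0, 0.5, 0.0, 0.0],
            [0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.5],
            [0.0, 0.0, 0.5, 1.0],
        ])
        assert np.allclose(cov, expected)
        assert not repaired

    def test_zero_correlations_identity(self):
        cov, _ = make_block_covariance((3, 2), 0.0, 0.0)
        assert np.allclose(cov, np.eye(5))

    def test_positive_definite_by_independent_eig(self):
        cov, _ = make_block_covariance((3, 3), 0.4, 0.1)
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_indefinite_matrix_repaired(self):
        # between-block coupling stronger than within forces repair
        cov, repaired = make_block_covariance((3, 3), 0.1, 0.8)
        assert repaired
        assert np.linalg.eigvalsh(cov)[0] >= -1e-10
        assert np.allclose(np.diag(cov), 1.0)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_block_covariance((3, 0), 0.4, 0.1)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError, match="-1, 1"):
            make_block_covariance((2, 2), 1.0, 0.0)

    def test_random_specs_always_psd(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            sizes = tuple(rng.integers(2, 6, size=3))
            rw = rng.uniform(-0.9, 0.9, size=3)
            rb = float(rng.uniform(-0.5, 0.5))
            cov, _ = make_block_covariance(sizes, rw, rb)
            assert np.linalg.eigvalsh(cov)[0] >= -1e-10


class TestTimeseriesSimulation:
    def test_identity_cov_near_zero_correlations(self):
        ts = simulate_subject_timeseries(np.eye(10), 5000, seed=11)
        r = np.corrcoef(ts.values, rowvar=False)
        off = r[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05 + 1e-3  # 3/sqrt(n) bound

    def test_same_seed_identical(self):
        cov, _ = make_block_covariance((3, 3), 0.3, 0.1)
        a = simulate_subject_timeseries(cov, 100, 0.3, seed=5)
        b = simulate_subject_timeseries(cov, 100, 0.3, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_block_correlation_recovered(self):
        cov, _ = make_block_covariance((5, 5), 0.4, 0.0)
        ts = simulate_subject_timeseries(cov, 5000, seed=3)
        r = np.corrcoef(ts.values, rowvar=False)
        within = [r[i, j] for b in (range(5), range(5, 10))
                  for i in b for j in b if i < j]
        assert 0.3 < np.mean(within) < 0.5

    def test_ar_coefficient_preserves_spatial_cov(self):
        cov, _ = make_block_covariance((5, 5), 0.4, 0.0)
        ts = simulate_subject_timeseries(cov, 5000, ar_coeff=0.5, seed=4)
        r = np.corrcoef(ts.values, rowvar=False)
        within = [r[i, j] for b in (range(5), range(5, 10))
                  for i in b for j in b if i < j]
        assert 0.3 < np.mean(within) < 0.5

    def test_non_psd_cov_rejected_with_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_subject_timeseries(bad, 10, seed=0)


class TestMotionSimulation:
    def test_zero_parameters_zero_fd(self):
        m = simulate_motion_trace(50, spike_prob=0.0, walk_sd=0.0,
                                  rot_walk_sd=0.0, seed=1)
        assert np.all(m.params == 0)
        assert np.all(framewise_displacement(m) == 0)

    def test_same_seed_identical(self):
        a = simulate_motion_trace(80, seed=2)
        b = simulate_motion_trace(80, seed=2)
        assert np.array_equal(a.params, b.params)

    def test_spike_count_within_binomial_interval(self):
        total = 0
        n_seeds, n_frames, p = 100, 120, 0.1
        for seed in range(n_seeds):
            m = simulate_motion_trace(n_frames, spike_prob=p, seed=seed)
            total += int((framewise_displacement(m) > 0.5).sum())
        n_eligible = n_seeds * (n_frames - 1)  # frame 0 has FD = 0
        lo = binom.ppf(0.005, n_eligible, p)
        hi = binom.ppf(0.995, n_eligible, p)
        assert lo <= total <= hi

    def test_invalid_spike_prob_rejected(self):
        with pytest.raises(ValueError):
            simulate_motion_trace(10, spike_prob=1.5)


def _patient_records(n=16):
    return [
        SubjectRecord(f"p{i}", "patient", 20.0, "M", duration_months=5.0)
        for i in range(n)
    ]


class TestClinicalCovariates:
    def test_noiseless_link_perfectly_correlated(self):
        recs = _patient_records(8)
        z = {f"p{i}": 0.1 * i for i in range(8)}
        out, info = assign_clinical_covariates(
            recs, z, ClinicalLink(intercept=5.0, slope=-1.0, noise_sd=0.0),
            seed=0,
        )
        freqs = [r.seizure_freq_per_day for r in out]
        r = np.corrcoef([z[f"p{i}"] for i in range(8)], freqs)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)
        assert info["planted_correlation_pre_truncation"] == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_default_link_recovers_negative_correlation(self):
        recs = _patient_records(16)
        negative = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            z = {f"p{i}": rng.normal(0.255, 0.03) for i in range(16)}
            out, _ = assign_clinical_covariates(recs, z, ClinicalLink(),
                                                seed=seed)
            r = np.corrcoef(
                [z[f"p{i}"] for i in range(16)],
                [o.seizure_freq_per_day for o in out],
            )[0, 1]
            negative += r < 0
        assert negative >= 0.95 * 200

    def test_null_link_behaves_like_null(self):
        recs = _patient_records(16)
        within = 0
        for seed in range(200):
            rng = np.random.default_rng(2000 + seed)
            z = {f"p{i}": rng.normal(0.255, 0.03) for i in range(16)}
            out, _ = assign_clinical_covariates(
                recs, z, ClinicalLink(intercept=13.0, slope=0.0,
                                      noise_sd=1.0),
                seed=seed,
            )
            r = np.corrcoef(
                [z[f"p{i}"] for i in range(16)],
                [o.seizure_freq_per_day for o in out],
            )[0, 1]
            within += abs(r) < 0.5
        assert within >= 0.9 * 200

    def test_frequencies_nonnegative(self):
        recs = _patient_records(16)
        rng = np.random.default_rng(3)
        z = {f"p{i}": rng.normal(0.255, 0.05) for i in range(16)}
        out, _ = assign_clinical_covariates(recs, z, seed=4)
        assert all(r.seizure_freq_per_day >= 0 for r in out)

    def test_no_patients_rejected(self):
        with pytest.raises(ValueError, match="no patients"):
            assign_clinical_covariates([], {}, seed=0)


class TestBenchmarkGraphs:
    def test_complete_graph(self):
        adj = benchmark_graph("complete", 4)
        assert adj.sum() // 2 == 6
        assert np.all(adj.sum(axis=0) == 3)

    def test_ring_lattice_degrees(self):
        adj = benchmark_graph("ring_lattice", 10, 4)
        assert np.all(adj.sum(axis=0) == 4)

    def test_erdos_renyi_edge_count_in_binomial_interval(self):
        adj = benchmark_graph("erdos_renyi", 160, 0.15, seed=5)
        m = int(adj.sum()) // 2
        n_pairs = 160 * 159 // 2
        assert binom.ppf(0.005, n_pairs, 0.15) <= m \
            <= binom.ppf(0.995, n_pairs, 0.15)

    def test_deterministic_given_seed(self):
        a = benchmark_graph("erdos_renyi", 50, 0.2, seed=9)
        b = benchmark_graph("erdos_renyi", 50, 0.2, seed=9)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kind,n,param",
        [("ring_lattice", 10, 3), ("ring_lattice", 10, 12),
         ("erdos_renyi", 10, 1.5), ("unknown", 10, None)],
    )
    def test_invalid_parameters_rejected(self, kind, n, param):
        with pytest.raises(ValueError):
            benchmark_graph(kind, n, param)


class TestCohortGeneration:
    def test_structure_and_determinism(self, tiny_spec, tiny_cohort):
        c2 = generate_cohort(tiny_spec)
        assert len(tiny_cohort.subjects) == 11
        for s1, s2 in zip(tiny_cohort.subjects, c2.subjects):
            assert np.array_equal(s1.timeseries.values, s2.timeseries.values)
            assert np.array_equal(s1.motion.params, s2.motion.params)
            assert s1.record == s2.record

    def test_controls_have_no_clinical_fields(self, tiny_cohort):
        for s in tiny_cohort.controls():
            assert s.record.seizure_freq_per_day is None
            assert s.record.duration_months is None
        for s in tiny_cohort.patients():
            assert s.record.seizure_freq_per_day is not None

    def test_planted_dmn_reduction_present(self, tiny_cohort):
        pz = [intra_module_mean_z(s.timeseries, tiny_cohort.partition)
              for s in tiny_cohort.patients()]
        cz = [intra_module_mean_z(s.timeseries, tiny_cohort.partition)
              for s in tiny_cohort.controls()]
        assert np.mean(pz) < np.mean(cz)

    def test_invalid_module_sizes_rejected(self):
        with pytest.raises(ValueError, match="n_rois"):
            CohortSpec(n_rois=100, module_sizes=(10, 10, 10, 10, 10, 10))

    def test_metadata_table_shape(self, tiny_cohort):
        md = tiny_cohort.metadata()
        assert set(md.columns) == {
            "subject_id", "group", "age_months", "sex",
            "seizure_freq_per_day", "duration_months",
        }
        assert (md.group == "patient").sum() == 5
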