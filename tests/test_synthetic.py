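"""Generator correctness: stationary moments, beat encoding, corruption truth."""

import numpy as np
import pytest
from scipy.stats import poisson

from dyadsync.ibi import beats_to_ibi, flag_and_correct, interpolate_4hz
from dyadsync.summary import analyzable_counts
from dyadsync.synthetic import (
    ArtifactSpec,
    CohortSpec,
    VARParams,
    corrupt_beats,
    make_cohort,
    simulate_beats_from_rsa,
    simulate_var_series,
)


def params_with(b_p2c=0.0, b_c2p=0.0, phi=0.4, sd=0.5, corr=0.2):
    cov = sd**2 * np.array([[1.0, corr], [corr, 1.0]])
    return VARParams(
        mu_parent=6.5,
        mu_child=6.0,
        phi_parent=phi,
        phi_child=phi,
        beta_parent_to_child=b_p2c,
        beta_child_to_parent=b_c2p,
        innovation_cov=cov,
    )


class TestVARParams:
    def test_nonstationary_transition_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            params_with(phi=0.8, b_p2c=0.5, b_c2p=0.5)

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            VARParams(6.5, 6.0, 0.4, 0.4, 0.0, 0.0, np.array([[1.0, 0.3], [0.1, 1.0]]))

    def test_indefinite_covariance_rejected(self):
        with pytest.raises(ValueError, match="semi-definite"):
            VARParams(6.5, 6.0, 0.4, 0.4, 0.0, 0.0, np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestSimulateVarSeries:
    def test_noise_free_null_process_is_constant(self):
        params = VARParams(6.5, 6.0, 0.0, 0.0, 0.0, 0.0, np.zeros((2, 2)))
        parent, child = simulate_var_series(params, 50, seed=0)
        assert np.allclose(parent, 6.5) and np.allclose(child, 6.0)

    def test_lag1_cross_covariance_matches_lyapunov_solution(self):
        # closed-form stationary moments are the oracle for the recursion
        params = params_with(b_c2p=0.3, b_p2c=0.1)
        n = 200_000
        parent, child = simulate_var_series(params, n, seed=42)
        dev = np.column_stack([parent, child]) - params.mean
        gamma1 = dev[1:].T @ dev[:-1] / (n - 1)
        expected = params.lag1_cross_cov()
        assert np.linalg.norm(gamma1 - expected) < 0.01 * np.linalg.norm(expected) + 1e-3

    def test_stationary_variance_matches_lyapunov_solution(self):
        params = params_with(b_c2p=0.3, b_p2c=-0.3)
        parent, child = simulate_var_series(params, 200_000, seed=3)
        emp = np.cov(np.column_stack([parent, child]).T)
        assert np.allclose(emp, params.stationary_cov(), rtol=0.03)

    def test_deterministic_under_seed(self):
        params = params_with(b_c2p=0.3)
        a = simulate_var_series(params, 500, seed=11)
        b = simulate_var_series(params, 500, seed=11)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_var_series(params_with(), 5, seed=0)


class TestSimulateBeats:
    def test_constant_rsa_gives_expected_modulation_depth(self):
        # A = sqrt(2 * 800) = 40 ms around an 800 ms base
        rsa = np.full(300, np.log(800.0))
        beats = simulate_beats_from_rsa(rsa, resp_freq=0.25, base_ibi=800.0)
        ibi = np.diff(beats.times) * 1000.0
        assert abs(ibi.mean() - 800.0) < 5.0
        assert abs(ibi.max() - 840.0) < 5.0
        assert abs(ibi.min() - 760.0) < 5.0

    def test_zero_amplitude_gives_regular_beats(self):
        rsa = np.full(60, -np.inf)
        beats = simulate_beats_from_rsa(rsa, resp_freq=0.25, base_ibi=750.0)
        assert np.allclose(np.diff(beats.times), 0.75)

    def test_nonphysical_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            simulate_beats_from_rsa(np.full(60, 13.0), resp_freq=0.25, base_ibi=800.0)

    def test_roundtrip_recovers_constant_rsa(self):
        # forward model -> IBI pipeline -> spectral stage closes the loop
        from dyadsync.spectral import estimate_rsa

        target = np.log(800.0)
        beats = simulate_beats_from_rsa(np.full(300, target), resp_freq=0.25, base_ibi=800.0)
        uniform = interpolate_4hz(flag_and_correct(beats_to_ibi(beats)), task_duration=300.0)
        rsa = estimate_rsa(uniform, role="parent")
        interior = rsa.valid_mask & (rsa.seconds >= 32) & (rsa.seconds <= 268)
        assert np.all(np.abs(rsa.values[interior] - target) < 0.1)


class TestCorruptBeats:
    def test_zero_rates_identity(self, regular_beats):
        out, truth = corrupt_beats(regular_beats, ArtifactSpec(), seed=0)
        assert np.array_equal(out.times, regular_beats.times)
        assert truth.corrupted_indices == () and truth.dropout_intervals == ()

    def test_dropout_recorded_and_masked_downstream(self, regular_beats):
        spec = ArtifactSpec(dropout_segments=((100.0, 12.0),))
        out, truth = corrupt_beats(regular_beats, spec, seed=1)
        assert truth.dropout_intervals == ((100.0, 112.0),)
        assert not np.any((out.times >= 100.0) & (out.times < 112.0))
        uniform = interpolate_4hz(flag_and_correct(beats_to_ibi(out)), task_duration=300.0)
        grid = uniform.times
        inside = (grid >= 101.0) & (grid < 111.0)
        assert not uniform.valid_mask[inside].any()
        assert uniform.valid_mask[grid < 99.0].all()
        assert uniform.valid_mask[(grid > 113.0) & (grid < 299.0)].all()

    def test_ectopic_count_within_poisson_bounds(self, regular_beats):
        # 2 events/min over 300 s: corrupted-beat count ~ Poisson(10)
        out, truth = corrupt_beats(regular_beats, ArtifactSpec(ectopic_rate=2.0), seed=7)
        lo, hi = poisson.ppf([0.005, 0.995], 10.0)
        assert lo <= len(truth.corrupted_indices) <= hi
        assert np.all(np.diff(out.times) > 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSpec(ectopic_rate=-1.0)
        with pytest.raises(ValueError):
            ArtifactSpec(run_length_probs=(0.5, 0.4))


class TestMakeCohort:
    def test_single_null_dyad_has_zero_cross_lags(self):
        spec = CohortSpec(
            n_dyads=1,
            regime_mix={
                "parent_driven": {"positive": 0, "negative": 0, "null": 1.0},
                "child_driven": {"positive": 0, "negative": 0, "null": 1.0},
            },
            task_labels=("conflict",),
            duration_s=120.0,
            seed=5,
        )
        cohort = make_cohort(spec)
        rec = cohort.records[0]
        assert rec.true_params.beta_parent_to_child == 0.0
        assert rec.true_params.beta_child_to_parent == 0.0
        assert rec.regime_parent_driven == "null"

    def test_exclusion_flags_reproduce_cohort_arithmetic(self):
        # 28 enrolled, 2 unusable in task 1, 1 more lost in task 2 -> 26/27/25
        spec = CohortSpec(
            n_dyads=28,
            duration_s=120.0,
            seed=9,
            unusable=(
                ("dyad001", "conflict"),
                ("dyad002", "conflict"),
                ("dyad003", "planning"),
            ),
        )
        cohort = make_cohort(spec)
        counts = analyzable_counts(
            [
                {"dyad_id": r.dyad_id, "task": r.task, "usable": r.usable}
                for r in cohort.records
            ]
        )
        assert counts.as_tuple("conflict", "planning") == (26, 27, 25)

    def test_deterministic_under_seed(self):
        spec = CohortSpec(n_dyads=2, duration_s=120.0, seed=13)
        a, b = make_cohort(spec), make_cohort(spec)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.parent_beats.times, rb.parent_beats.times)
            assert np.array_equal(ra.true_rsa_child, rb.true_rsa_child)
            assert ra.regime_child_driven == rb.regime_child_driven

    def test_invalid_regime_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(
                n_dyads=2,
                duration_s=120.0,
                regime_mix={
                    "parent_driven": {"positive": 0.8, "negative": 0.8, "null": 0.0},
                    "child_driven": {"positive": 0, "negative": 0, "null": 1.0},
                },
            )
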