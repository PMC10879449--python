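"""Simulation studies validating the estimation stages against known truth.

These are the package's calibration experiments: cross-lag parameter recovery
and credible-interval coverage for the dyadic lag-1 model, the false-non-null
rate of the CrI classification rule under null coupling, the empirical size
of the ADF screen on unit-root data, and the spectral round trip from encoded
beats back to band power.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dsem import DyadTaskRecord, MCMCConfig, classify_synchrony, fit_dyad_var
from .ibi import beats_to_ibi, flag_and_correct, interpolate_4hz
from .spectral import BandSpec, RSASeries, SpectralConfig, estimate_rsa
from .stationarity import adf_test
from .synthetic import VARParams, simulate_beats_from_rsa, simulate_var_series

__all__ = [
    "RecoveryStudy",
    "crosslag_recovery_study",
    "adf_size_study",
    "spectral_roundtrip_study",
    "default_var_params",
    "rsa_record_from_series",
]

_CROSS_LAG_NAMES = ("beta_parent_to_child", "beta_child_to_parent")


def default_var_params(
    beta_parent_to_child: float = 0.0,
    beta_child_to_parent: float = 0.0,
    phi: float = 0.4,
    innovation_sd: float = 0.5,
    innovation_corr: float = 0.2,
) -> VARParams:
    """Study-condition VAR parameters: moderate stability, configurable coupling."""
    cov = innovation_sd**2 * np.array([[1.0, innovation_corr], [innovation_corr, 1.0]])
    return VARParams(
        mu_parent=6.5,
        mu_child=6.0,
        phi_parent=phi,
        phi_child=phi,
        beta_parent_to_child=beta_parent_to_child,
        beta_child_to_parent=beta_child_to_parent,
        innovation_cov=cov,
    )


def rsa_record_from_series(
    parent: np.ndarray,
    child: np.ndarray,
    dyad_id: str = "sim",
    task: str = "task",
    valid_mask: np.ndarray | None = None,
) -> DyadTaskRecord:
    """Wrap directly simulated RSA series as a model-ready dyad-task record."""
    n = parent.size
    seconds = np.arange(n)
    band = BandSpec(0.12, 0.40, "adult")
    if valid_mask is None:
        valid_mask = np.ones(n, dtype=bool)
    pv = np.where(valid_mask, parent, np.nan)
    cv = np.where(valid_mask, child, np.nan)
    return DyadTaskRecord(
        dyad_id=dyad_id,
        task=task,
        parent_rsa=RSASeries(seconds=seconds, values=pv, valid_mask=valid_mask, band=band),
        child_rsa=RSASeries(seconds=seconds, values=cv, valid_mask=valid_mask, band=band),
    )


@dataclass
class RecoveryStudy:
    """Pooled results of the cross-lag recovery / calibration simulation."""

    regimes: tuple[float, ...]
    n_reps: dict[float, int]
    median_bias: dict[tuple[float, str], float] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)  # pooled over regimes
    false_nonnull_rate: dict[str, float] = field(default_factory=dict)  # null regime
    n_coverage_trials: int = 0
    n_null_reps: int = 0
    mean_discarded_fraction: float = 0.0

    @property
    def max_abs_median_bias(self) -> float:
        return max(abs(v) for v in self.median_bias.values())


def _fit_config(seed: int, max_iterations: int, min_iterations: int) -> MCMCConfig:
    return MCMCConfig(
        n_chains=2,
        max_iterations=max_iterations,
        min_iterations=min_iterations,
        check_interval=250,
        seed=seed,
    )


def crosslag_recovery_study(
    seed: int = 0,
    regimes: tuple[float, ...] = (-0.3, 0.0, 0.3),
    n_reps_regime: int = 100,
    n_reps_null: int = 400,
    n_seconds: int = 300,
    max_iterations: int = 3000,
    min_iterations: int = 1500,
) -> RecoveryStudy:
    """Parameter recovery and CrI calibration for the dyadic lag-1 model.

    For each regime both cross-lags are set to the regime value; each
    replicate simulates one dyad at the study length, fits the model, and
    records the posterior medians, CrI coverage of the true cross-lags, and
    (for the null regime) whether the CrI rule produced a false non-null call.
    Coverage is pooled over all regimes; bias is tracked per regime.
    """
    root = np.random.SeedSequence(seed)
    study = RecoveryStudy(regimes=regimes, n_reps={})
    errors: dict[tuple[float, str], list[float]] = {}
    covered: dict[str, int] = {name: 0 for name in _CROSS_LAG_NAMES}
    false_nonnull: dict[str, int] = {name: 0 for name in _CROSS_LAG_NAMES}
    n_cov = 0
    discarded: list[float] = []

    for regime in regimes:
        n_reps = n_reps_null if regime == 0.0 else n_reps_regime
        study.n_reps[regime] = n_reps
        params = default_var_params(
            beta_parent_to_child=regime, beta_child_to_parent=regime
        )
        for rep_ss in root.spawn(n_reps):
            sim_ss, fit_ss = rep_ss.spawn(2)
            parent, child = simulate_var_series(params, n_seconds, sim_ss)
            record = rsa_record_from_series(parent, child)
            fit_seed = int(fit_ss.generate_state(1)[0] % (2**31))
            post = fit_dyad_var(
                record, _fit_config(fit_seed, max_iterations, min_iterations)
            )
            discarded.append(post.discarded_fraction)
            n_cov += 1
            for name in _CROSS_LAG_NAMES:
                s = post.params[name]
                errors.setdefault((regime, name), []).append(s.median - regime)
                if s.cri_low <= regime <= s.cri_high:
                    covered[name] += 1
            for name in ("phi_parent", "phi_child"):
                errors.setdefault((regime, name), []).append(
                    post.params[name].median - params.phi_parent
                )
            if regime == 0.0:
                call = classify_synchrony(post)
                if call.parent_driven != "null":
                    false_nonnull["beta_parent_to_child"] += 1
                if call.child_driven != "null":
                    false_nonnull["beta_child_to_parent"] += 1

    study.median_bias = {
        key: float(np.median(vals)) for key, vals in errors.items()
    }
    study.coverage = {name: covered[name] / n_cov for name in _CROSS_LAG_NAMES}
    study.n_coverage_trials = n_cov
    study.n_null_reps = study.n_reps.get(0.0, 0)
    if study.n_null_reps:
        study.false_nonnull_rate = {
            name: false_nonnull[name] / study.n_null_reps for name in _CROSS_LAG_NAMES
        }
    study.mean_discarded_fraction = float(np.mean(discarded))
    return study


def adf_size_study(
    seed: int = 0,
    n_reps: int = 2000,
    n_obs: int = 300,
    alpha: float = 0.05,
    model: str = "single-mean",
) -> float:
    """Empirical rejection rate of the lag-1 ADF test on pure random walks.

    Under the unit-root null the rejection rate should match the nominal
    alpha; returns the empirical size as a fraction.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        walk = np.cumsum(rng.standard_normal(n_obs))
        res = adf_test(walk, model=model, lags=1, alpha=alpha)
        rejections += res.reject_unit_root
    return rejections / n_reps


def spectral_roundtrip_study(
    rsa_value: float = float(np.log(800.0)),
    resp_freq: float = 0.25,
    base_ibi: float = 800.0,
    duration_s: int = 300,
    config: SpectralConfig | None = None,
) -> dict:
    """Constant-RSA round trip: beats -> IBI -> 4 Hz -> band power.

    Encodes a constant log band power into beat times and measures the mean
    recovered band power over interior seconds plus the worst-case absolute
    log error, against the analytic target exp(rsa_value).
    """
    rsa_target = np.full(duration_s, rsa_value)
    beats = simulate_beats_from_rsa(rsa_target, resp_freq=resp_freq, base_ibi=base_ibi)
    uniform = interpolate_4hz(flag_and_correct(beats_to_ibi(beats)), task_duration=duration_s)
    rsa = estimate_rsa(uniform, role="parent", config=config)
    interior = rsa.valid_mask & (rsa.seconds >= 32) & (rsa.seconds <= duration_s - 32)
    recovered = np.exp(rsa.values[interior])
    return {
        "target_power_ms2": float(np.exp(rsa_value)),
        "mean_power_ms2": float(np.mean(recovered)),
        "max_abs_log_error": float(np.max(np.abs(rsa.values[interior] - rsa_value))),
        "n_seconds": int(interior.sum()),
    }
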