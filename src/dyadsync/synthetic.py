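"""Synthetic dyadic cardiac data with known ground truth.

Ground truth is defined at the RSA level: each dyad-task is a draw from a
stationary bivariate lag-1 (VAR(1)) process in log band power, and beat times
are then generated so that the heart-period signal carries a respiratory-band
sinusoid whose local power equals the target RSA trajectory.  A sinusoid of
amplitude A has power A^2/2, so the modulation amplitude at time t is
A(t) = sqrt(2 * exp(rsa(t))); running the beat series through the IBI and
spectral stages should therefore recover the simulated RSA, which makes every
stage of the pipeline testable against an analytic target.  Beat-level
corruption (ectopic displacement runs, dropout segments) emulates movement
artifact and equipment loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .ibi import BeatSeries

__all__ = [
    "VARParams",
    "ArtifactSpec",
    "CohortSpec",
    "CorruptionTruth",
    "DyadTaskFixture",
    "Cohort",
    "simulate_var_series",
    "simulate_beats_from_rsa",
    "corrupt_beats",
    "make_cohort",
    "REGIMES",
]

REGIMES = ("positive", "negative", "null")


@dataclass(frozen=True)
class VARParams:
    """Parameters of the bivariate lag-1 RSA process for one dyad.

    State order is (parent, child); the transition matrix row for the parent
    equation is ``[phi_parent, beta_child_to_parent]`` so that the child's
    deviation at t-1 feeds the parent at t (child-driven synchrony), and
    symmetrically for the child equation.
    """

    mu_parent: float
    mu_child: float
    phi_parent: float
    phi_child: float
    beta_parent_to_child: float
    beta_child_to_parent: float
    innovation_cov: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.innovation_cov, dtype=float)
        object.__setattr__(self, "innovation_cov", cov)
        if cov.shape != (2, 2):
            raise ValueError("innovation_cov must be 2x2")
        if not np.allclose(cov, cov.T):
            raise ValueError("innovation_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("innovation_cov must be positive semi-definite")
        if np.max(np.abs(np.linalg.eigvals(self.transition_matrix))) >= 1.0:
            raise ValueError(
                "transition matrix must have spectral radius < 1 (stationary process)"
            )

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.phi_parent, self.beta_child_to_parent],
                [self.beta_parent_to_child, self.phi_child],
            ]
        )

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_parent, self.mu_child])

    def stationary_cov(self) -> np.ndarray:
        """Closed-form stationary covariance via the discrete Lyapunov equation."""
        return solve_discrete_lyapunov(self.transition_matrix, self.innovation_cov)

    def lag1_cross_cov(self) -> np.ndarray:
        """Stationary lag-1 cross-covariance Cov(s_t, s_{t-1}) = Phi @ S."""
        return self.transition_matrix @ self.stationary_cov()


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of semi-definite (including zero) covariance."""
    vals, vecs = np.linalg.eigh(cov)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_var_series(
    params: VARParams, n_seconds: int, seed: int | np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate paired per-second RSA series (parent, child) in ln ms^2.

    The initial state is drawn from the stationary distribution, so the whole
    trajectory is stationary; output is reproducible under a fixed seed.
    """
    if n_seconds < 10:
        raise ValueError("n_seconds must be at least 10")
    rng = np.random.default_rng(seed)
    phi = params.transition_matrix
    mean = params.mean
    innov_factor = _psd_factor(params.innovation_cov)
    init_factor = _psd_factor(params.stationary_cov())

    out = np.empty((n_seconds, 2))
    dev = init_factor @ rng.standard_normal(2)
    out[0] = mean + dev
    shocks = rng.standard_normal((n_seconds - 1, 2)) @ innov_factor.T
    for t in range(1, n_seconds):
        dev = phi @ dev + shocks[t - 1]
        out[t] = mean + dev
    return out[:, 0], out[:, 1]


def simulate_beats_from_rsa(
    rsa_target: np.ndarray,
    resp_freq: float,
    base_ibi: float,
    seed: int | None = None,
    jitter_ms: float = 0.0,
) -> BeatSeries:
    """Emit beat times whose IBI carries a respiratory sinusoid encoding RSA.

    The continuous heart-period signal is ``base_ibi + A(t) sin(2 pi f t)``
    with ``A(t) = sqrt(2 exp(rsa(t)))`` so local band power equals
    ``exp(rsa(t))``.  ``rsa_target`` gives one value per second; it is linearly
    interpolated between second centres.  Optional Gaussian timing jitter of
    ``jitter_ms`` ms per beat emulates detection noise.
    """
    rsa = np.asarray(rsa_target, dtype=float)
    if rsa.ndim != 1 or rsa.size < 1:
        raise ValueError("rsa_target must be a non-empty 1-D array")
    if not 300.0 <= base_ibi <= 1500.0:
        raise ValueError("base_ibi must be within [300, 1500] ms")
    amplitude = np.sqrt(2.0 * np.exp(rsa))
    if np.any(amplitude >= base_ibi):
        raise ValueError(
            "rsa_target implies modulation amplitude >= base IBI (negative heart period)"
        )
    duration = float(rsa.size)
    rng = np.random.default_rng(seed) if jitter_ms > 0 else None

    sec_grid = np.arange(rsa.size, dtype=float)
    times = [0.0]
    t = 0.0
    while True:
        a = float(np.interp(t, sec_grid, amplitude))
        ibi_s = (base_ibi + a * np.sin(2 * np.pi * resp_freq * t)) / 1000.0
        t += ibi_s
        if t >= duration:
            break
        beat = t
        if rng is not None:
            beat = beat + rng.normal(0.0, jitter_ms / 1000.0)
            beat = max(beat, times[-1] + 1e-3)
        times.append(beat)
    return BeatSeries(times=np.array(times))


@dataclass(frozen=True)
class ArtifactSpec:
    """Beat-level corruption: ectopic displacement events and dropout segments.

    ``run_length_probs[k]`` is the probability that one ectopic event corrupts
    k+1 consecutive beats.
    """

    ectopic_rate: float = 0.0  # expected events per minute
    run_length_probs: tuple[float, ...] = (1.0,)
    dropout_segments: tuple[tuple[float, float], ...] = ()  # (start s, duration s)

    def __post_init__(self) -> None:
        if self.ectopic_rate < 0:
            raise ValueError("ectopic_rate must be non-negative")
        probs = np.asarray(self.run_length_probs, dtype=float)
        if probs.size == 0 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("run_length_probs must be a probability vector")
        for start, dur in self.dropout_segments:
            if dur <= 0:
                raise ValueError("dropout durations must be positive")
            if start < 0:
                raise ValueError("dropout segments must start within the task")


@dataclass(frozen=True)
class CorruptionTruth:
    """Ground-truth record of which beats/intervals were corrupted."""

    corrupted_indices: tuple[int, ...]
    dropout_intervals: tuple[tuple[float, float], ...]  # (start s, end s)


def corrupt_beats(
    beats: BeatSeries, spec: ArtifactSpec, seed: int | None = None
) -> tuple[BeatSeries, CorruptionTruth]:
    """Apply artifact corruption to a beat series, returning the truth map."""
    rng = np.random.default_rng(seed)
    times = beats.times.copy()
    n = times.size
    corrupted: set[int] = set()

    for start, dur in spec.dropout_segments:
        if start + dur > beats.duration + 1e-9:
            raise ValueError("dropout segment extends beyond the recording")

    n_events = rng.poisson(spec.ectopic_rate * beats.duration / 60.0)
    lengths = np.arange(1, len(spec.run_length_probs) + 1)
    for _ in range(n_events):
        if n < 4:
            break
        run = int(rng.choice(lengths, p=spec.run_length_probs))
        start_idx = int(rng.integers(1, max(2, n - run - 1)))
        for i in range(start_idx, min(start_idx + run, n - 1)):
            gap = min(times[i] - times[i - 1], times[i + 1] - times[i])
            shift = rng.uniform(0.25, 0.45) * gap * rng.choice([-1.0, 1.0])
            times[i] = times[i] + shift
            corrupted.add(i)
    # displacement is bounded by 0.45 of the adjacent gaps, so order holds
    dropout_intervals = []
    keep = np.ones(n, dtype=bool)
    for start, dur in spec.dropout_segments:
        end = start + dur
        keep &= ~((times >= start) & (times < end))
        dropout_intervals.append((float(start), float(end)))

    return (
        BeatSeries(times=times[keep]),
        CorruptionTruth(
            corrupted_indices=tuple(sorted(corrupted)),
            dropout_intervals=tuple(dropout_intervals),
        ),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort of dyads over one or more tasks.

    ``regime_mix`` maps each coupling direction to the probabilities with
    which a dyad-task is assigned a positive, negative, or null cross-lag.
    ``unusable`` marks (dyad_id, task) pairs excluded from analysis, standing
    in for records lost to artifact or equipment failure.
    """

    n_dyads: int = 28
    regime_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "parent_driven": {"positive": 0.25, "negative": 0.25, "null": 0.5},
            "child_driven": {"positive": 0.25, "negative": 0.25, "null": 0.5},
        }
    )
    task_labels: tuple[str, ...] = ("conflict", "planning")
    duration_s: float = 300.0
    seed: int = 0
    effect_size: float = 0.3
    phi: float = 0.4
    mu_parent: float = 6.5
    mu_child: float = 6.0
    innovation_sd: float = 0.5
    innovation_corr: float = 0.2
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    unusable: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be at least 1")
        if self.duration_s < 64:
            raise ValueError("duration_s too short for 32-s spectral windows")
        for direction in ("parent_driven", "child_driven"):
            mix = self.regime_mix.get(direction)
            if mix is None:
                raise ValueError(f"regime_mix missing direction {direction!r}")
            probs = [mix.get(r, 0.0) for r in REGIMES]
            if any(p < 0 or p > 1 for p in probs) or not np.isclose(sum(probs), 1.0):
                raise ValueError(f"regime_mix[{direction!r}] must sum to 1")


@dataclass(frozen=True)
class DyadTaskFixture:
    dyad_id: str
    task: str
    child_age: float
    parent_beats: BeatSeries
    child_beats: BeatSeries
    parent_truth: CorruptionTruth
    child_truth: CorruptionTruth
    true_params: VARParams
    true_rsa_parent: np.ndarray
    true_rsa_child: np.ndarray
    regime_parent_driven: str
    regime_child_driven: str
    usable: bool


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    records: tuple[DyadTaskFixture, ...]

    def record(self, dyad_id: str, task: str) -> DyadTaskFixture:
        for r in self.records:
            if r.dyad_id == dyad_id and r.task == task:
                return r
        raise KeyError((dyad_id, task))

    @property
    def dyad_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.records:
            if r.dyad_id not in seen:
                seen.append(r.dyad_id)
        return tuple(seen)


def _beta_for(regime: str, effect_size: float) -> float:
    return {"positive": effect_size, "negative": -effect_size, "null": 0.0}[regime]


def make_cohort(spec: CohortSpec) -> Cohort:
    """Assemble a deterministic cohort fixture from a cohort design.

    Each dyad-task gets its own regime draw, VAR parameters, simulated RSA
    trajectories, encoded beat series for both roles, and artifact corruption.
    """
    root = np.random.SeedSequence(spec.seed)
    cov = spec.innovation_sd**2 * np.array(
        [[1.0, spec.innovation_corr], [spec.innovation_corr, 1.0]]
    )
    unusable = set(spec.unusable)
    records: list[DyadTaskFixture] = []
    n_seconds = int(round(spec.duration_s))

    for d, dyad_ss in enumerate(root.spawn(spec.n_dyads)):
        dyad_id = f"dyad{d + 1:03d}"
        streams = dyad_ss.spawn(len(spec.task_labels))
        age_rng = np.random.default_rng(dyad_ss)
        child_age = float(age_rng.integers(6, 12))
        for task, task_ss in zip(spec.task_labels, streams):
            rng = np.random.default_rng(task_ss)
            regime_pd = str(
                rng.choice(REGIMES, p=[spec.regime_mix["parent_driven"][r] for r in REGIMES])
            )
            regime_cd = str(
                rng.choice(REGIMES, p=[spec.regime_mix["child_driven"][r] for r in REGIMES])
            )
            params = VARParams(
                mu_parent=spec.mu_parent,
                mu_child=spec.mu_child,
                phi_parent=spec.phi,
                phi_child=spec.phi,
                beta_parent_to_child=_beta_for(regime_pd, spec.effect_size),
                beta_child_to_parent=_beta_for(regime_cd, spec.effect_size),
                innovation_cov=cov,
            )
            sim_ss, pb_ss, cb_ss, pa_ss, ca_ss = task_ss.spawn(5)
            rsa_p, rsa_c = simulate_var_series(params, n_seconds, sim_ss)
            parent_beats = simulate_beats_from_rsa(rsa_p, resp_freq=0.25, base_ibi=800.0)
            child_beats = simulate_beats_from_rsa(rsa_c, resp_freq=0.30, base_ibi=600.0)
            parent_beats, parent_truth = corrupt_beats(
                parent_beats, spec.artifacts, seed=pa_ss.generate_state(1)[0] % (2**31)
            )
            child_beats, child_truth = corrupt_beats(
                child_beats, spec.artifacts, seed=ca_ss.generate_state(1)[0] % (2**31)
            )
            records.append(
                DyadTaskFixture(
                    dyad_id=dyad_id,
                    task=task,
                    child_age=child_age,
                    parent_beats=parent_beats,
                    child_beats=child_beats,
                    parent_truth=parent_truth,
                    child_truth=child_truth,
                    true_params=params,
                    true_rsa_parent=rsa_p,
                    true_rsa_child=rsa_c,
                    regime_parent_driven=regime_pd,
                    regime_child_driven=regime_cd,
                    usable=(dyad_id, task) not in unusable,
                )
            )
    return Cohort(spec=spec, records=tuple(records))
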