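"""Per-dyad Bayesian bivariate lag-1 dynamic model and synchrony classification.

For one dyad and task the model is a latent-mean-centred VAR(1) on the paired
per-second RSA series ``y_t = (parent_t, child_t)``::

    y_t - mu = Phi (y_{t-1} - mu) + e_t,      e_t ~ N(0, Sigma)

with ``Phi = [[phi_parent, beta_child_to_parent],
              [beta_parent_to_child, phi_child]]``.

The off-diagonal cross-lags are the synchrony parameters: a child-driven
effect is the influence of the child's RSA deviation at one second on the
parent's deviation the next second, adjusting for the parent's own prior
deviation, and symmetrically for the parent-driven effect.  The means are
sampled jointly with the dynamics (latent mean centring) rather than removed
by pre-subtracting sample averages, so lagged effects operate on deviations
from an estimated trait level.

Estimation is a blocked Gibbs sampler with conditionally conjugate diffuse
priors: normal (mean 0, variance 1e6) on means and dynamic coefficients, and
inverse-Wishart (identity scale, 3 degrees of freedom) on the innovation
covariance.  Missing seconds are handled by data augmentation.  Two or more
chains run from dispersed starts; at periodic checkpoints the Gelman-Rubin
potential scale reduction (PSR) factor is computed for every parameter and
sampling terminates early once all fall below the threshold.  Posterior draws
whose standardized autoregressive coefficients exceed 1 in magnitude (or whose
transition matrix is non-stationary) are discarded as inadmissible before
summarizing; summaries are medians and equal-tailed credible intervals.

A cross-lag is classified non-null (positive or negative) when its credible
interval excludes zero; an endpoint exactly at zero counts as containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnusableRecordError
from .spectral import RSASeries

__all__ = [
    "DyadTaskRecord",
    "MCMCConfig",
    "ParamSummary",
    "VARPosterior",
    "SynchronyCall",
    "PSRResult",
    "fit_dyad_var",
    "psr",
    "classify_synchrony",
    "PARAM_NAMES",
    "MIN_VALID_SECONDS",
]

PARAM_NAMES = (
    "mu_parent",
    "mu_child",
    "phi_parent",
    "phi_child",
    "beta_parent_to_child",
    "beta_child_to_parent",
    "innovation_var_parent",
    "innovation_var_child",
    "innovation_cov",
)

MIN_VALID_SECONDS = 50


@dataclass(frozen=True)
class DyadTaskRecord:
    """Aligned parent/child RSA series for one dyad-task, on one 1-s grid."""

    dyad_id: str
    task: str
    parent_rsa: RSASeries
    child_rsa: RSASeries

    def __post_init__(self) -> None:
        p, c = self.parent_rsa, self.child_rsa
        if not np.array_equal(p.seconds, c.seconds):
            raise ValueError("parent and child RSA must share the same second grid")
        if p.seconds.size > 1 and not np.all(np.diff(p.seconds) == 1):
            raise ValueError("second grid must be contiguous (1-s steps)")
        both = p.valid_mask & c.valid_mask
        if both.sum() < MIN_VALID_SECONDS:
            raise UnusableRecordError(
                f"need at least {MIN_VALID_SECONDS} seconds valid in both series, "
                f"got {int(both.sum())}"
            )

    @property
    def y(self) -> np.ndarray:
        return np.column_stack([self.parent_rsa.values, self.child_rsa.values])

    @property
    def obs_mask(self) -> np.ndarray:
        return np.column_stack([self.parent_rsa.valid_mask, self.child_rsa.valid_mask])


@dataclass(frozen=True)
class MCMCConfig:
    """Gibbs sampler settings.

    ``max_iterations`` is a ceiling; sampling stops at the first checkpoint
    (every ``check_interval`` iterations, after ``min_iterations``) at which
    every parameter's PSR is below ``psr_threshold``.
    """

    n_chains: int = 2
    max_iterations: int = 100_000
    min_iterations: int = 1_000
    check_interval: int = 500
    psr_threshold: float = 1.05
    burn_in_fraction: float = 0.5
    cri_level: float = 0.95
    seed: int = 0
    prior_mean_variance: float = 1e6
    prior_coef_variance: float = 1e6
    prior_wishart_df: float = 3.0
    fix_dynamics: bool = False  # conjugate reduction: Phi pinned at 0
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for the PSR diagnostic")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.psr_threshold <= 1.0:
            raise ValueError("psr_threshold must exceed 1")
        if not 0.0 < self.cri_level < 1.0:
            raise ValueError("cri_level must be in (0, 1)")
        if self.min_iterations > self.max_iterations:
            raise ValueError("min_iterations cannot exceed max_iterations")


@dataclass(frozen=True)
class ParamSummary:
    median: float
    cri_low: float
    cri_high: float
    psr: float

    def __post_init__(self) -> None:
        if not self.cri_low <= self.median <= self.cri_high:
            raise ValueError("credible interval must bracket the median")


@dataclass(frozen=True)
class VARPosterior:
    dyad_id: str
    task: str
    params: dict[str, ParamSummary]
    discarded_fraction: float
    n_iterations_used: int
    converged: bool
    cri_level: float
    degenerate_params: tuple[str, ...] = ()
    draws: np.ndarray | None = None  # (n_chains, n_kept, n_params) when kept


@dataclass(frozen=True)
class SynchronyCall:
    dyad_id: str
    task: str
    parent_driven: str  # positive | negative | null
    child_driven: str
    converged: bool = True


@dataclass(frozen=True)
class PSRResult:
    values: np.ndarray
    degenerate: np.ndarray


def psr(chains: np.ndarray) -> PSRResult:
    """Gelman-Rubin potential scale reduction from the second half of each chain.

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws, n_params).
    Zero-variance (degenerate) parameters are reported as PSR 1 with a flag.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n_total, p = arr.shape
    if m < 2:
        raise ValueError("PSR requires at least 2 chains")
    half = arr[:, n_total // 2 :, :]
    n = half.shape[1]
    if n < 5:
        raise ValueError("PSR requires at least 10 draws per chain")
    chain_means = half.mean(axis=1)  # (m, p)
    chain_vars = half.var(axis=1, ddof=1)  # (m, p)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    degenerate = w <= 1e-300
    w_safe = np.where(degenerate, 1.0, w)
    v_hat = (n - 1) / n * w_safe + (1.0 + 1.0 / m) * b / n
    # values below 1 are estimation noise; report the floor
    values = np.maximum(np.sqrt(v_hat / w_safe), 1.0)
    values = np.where(degenerate, 1.0, values)
    return PSRResult(values=values, degenerate=degenerate)


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _inv_wishart_2x2(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw Sigma ~ InvWishart(df, scale) via a Bartlett-decomposed Wishart."""
    l = np.linalg.cholesky(_inv2(scale))
    a = np.zeros((2, 2))
    a[0, 0] = np.sqrt(rng.chisquare(df))
    a[1, 1] = np.sqrt(rng.chisquare(df - 1))
    a[1, 0] = rng.standard_normal()
    la = l @ a
    w = la @ la.T
    sigma = _inv2(w)
    return (sigma + sigma.T) / 2.0


def _gibbs_step(
    state: dict,
    rng: np.random.Generator,
    obs_mask: np.ndarray,
    missing_ts: np.ndarray,
    config: MCMCConfig,
) -> None:
    """One full Gibbs scan, updating ``state`` in place.

    Coefficients use the row convention ``(y_t - mu)' = (y_{t-1} - mu)' B + e'``
    so the transition matrix is ``Phi = B.T``.
    """
    y = state["y"]
    mu = state["mu"]
    b = state["B"]
    sigma = state["Sigma"]
    n = y.shape[0] - 1

    siginv = _inv2(sigma)

    # --- dynamic coefficients | mu, Sigma, y ---
    w_mat = y[:-1] - mu
    z_mat = y[1:] - mu
    if not config.fix_dynamics:
        wtw = w_mat.T @ w_mat
        wtz = w_mat.T @ z_mat
        prec = np.kron(siginv, wtw)
        prec[np.diag_indices(4)] += 1.0 / config.prior_coef_variance
        h = (wtz @ siginv).reshape(4, order="F")
        cov_b = np.linalg.inv(prec)
        mean_b = cov_b @ h
        draw = mean_b + np.linalg.cholesky((cov_b + cov_b.T) / 2.0) @ rng.standard_normal(4)
        b = draw.reshape(2, 2, order="F")
        state["B"] = b

    # --- means | B, Sigma, y ---
    phi = b.T
    m_mat = np.eye(2) - phi
    resid_sum = (y[1:] - y[:-1] @ b).sum(axis=0)
    prec_mu = n * m_mat.T @ siginv @ m_mat + np.eye(2) / config.prior_mean_variance
    h_mu = m_mat.T @ siginv @ resid_sum
    cov_mu = np.linalg.inv(prec_mu)
    mean_mu = cov_mu @ h_mu
    mu = mean_mu + np.linalg.cholesky((cov_mu + cov_mu.T) / 2.0) @ rng.standard_normal(2)
    state["mu"] = mu

    # --- innovation covariance | B, mu, y ---
    e_mat = (y[1:] - mu) - (y[:-1] - mu) @ b
    scale = np.eye(2) + e_mat.T @ e_mat
    sigma = _inv_wishart_2x2(rng, config.prior_wishart_df + n, scale)
    state["Sigma"] = sigma

    # --- missing data | B, mu, Sigma ---
    if missing_ts.size:
        siginv = _inv2(sigma)
        phi = b.T
        pts = siginv + phi.T @ siginv @ phi
        t_max = y.shape[0] - 1
        for t in missing_ts:
            if t > 0:
                a = mu + phi @ (y[t - 1] - mu)
            else:
                a = mu  # stationary-mean prior for a missing initial second
            if t < t_max:
                prec_t = pts
                c = y[t + 1] - mu + phi @ mu
                h_t = siginv @ a + phi.T @ siginv @ c
            else:
                prec_t = siginv
                h_t = siginv @ a
            miss = ~obs_mask[t]
            if miss.all():
                cov_t = _inv2(prec_t)
                y[t] = cov_t @ h_t + np.linalg.cholesky(
                    (cov_t + cov_t.T) / 2.0
                ) @ rng.standard_normal(2)
            else:
                i = int(np.flatnonzero(miss)[0])
                j = 1 - i
                var_i = 1.0 / prec_t[i, i]
                mean_i = (h_t[i] - prec_t[i, j] * y[t, j]) * var_i
                y[t, i] = mean_i + np.sqrt(var_i) * rng.standard_normal()


def _extract_params(state: dict) -> np.ndarray:
    b = state["B"]
    mu = state["mu"]
    sigma = state["Sigma"]
    # Phi = B.T: Phi[0,1] is child->parent, Phi[1,0] is parent->child
    return np.array(
        [
            mu[0],
            mu[1],
            b[0, 0],
            b[1, 1],
            b[0, 1],
            b[1, 0],
            sigma[0, 0],
            sigma[1, 1],
            sigma[0, 1],
        ]
    )


def _admissible_mask(pooled: np.ndarray) -> np.ndarray:
    """Flag draws whose standardized autoregressive coefficients exceed 1.

    The standardization scales each cross-lag by the ratio of the two series'
    implied stationary standard deviations under that draw's dynamics; draws
    with a non-stationary transition matrix are inadmissible outright.
    """
    n = pooled.shape[0]
    phi = np.empty((n, 2, 2))
    phi[:, 0, 0] = pooled[:, 2]
    phi[:, 1, 1] = pooled[:, 3]
    phi[:, 1, 0] = pooled[:, 4]  # parent -> child
    phi[:, 0, 1] = pooled[:, 5]  # child -> parent
    sig = np.empty((n, 2, 2))
    sig[:, 0, 0] = pooled[:, 6]
    sig[:, 1, 1] = pooled[:, 7]
    sig[:, 0, 1] = sig[:, 1, 0] = pooled[:, 8]

    eigmax = np.max(np.abs(np.linalg.eigvals(phi)), axis=1)
    stationary = eigmax < 1.0 - 1e-9

    admissible = stationary.copy()
    if stationary.any():
        phis = phi[stationary]
        kron = np.einsum("nij,nkl->nikjl", phis, phis).reshape(-1, 4, 4)
        rhs = sig[stationary].reshape(-1, 4)
        svec = np.linalg.solve(np.eye(4) - kron, rhs[..., None])[..., 0]
        s_pp, s_cc = svec[:, 0], svec[:, 3]
        ok = (s_pp > 0) & (s_cc > 0)
        ratio = np.sqrt(np.where(ok, s_cc, 1.0) / np.where(ok, s_pp, 1.0))
        std_coeffs = np.stack(
            [
                np.abs(phis[:, 0, 0]),
                np.abs(phis[:, 1, 1]),
                np.abs(phis[:, 1, 0]) / ratio,  # parent->child scaled by sd_p/sd_c
                np.abs(phis[:, 0, 1]) * ratio,  # child->parent scaled by sd_c/sd_p
            ]
        )
        admissible[stationary] = ok & np.all(std_coeffs <= 1.0, axis=0)
    return admissible


def fit_dyad_var(record: DyadTaskRecord, config: MCMCConfig | None = None) -> VARPosterior:
    """Fit the dyadic lag-1 model by blocked Gibbs sampling.

    Returns posterior summaries for the six mean/dynamic parameters and the
    innovation covariance.  Non-convergence (PSR at or above threshold at
    ``max_iterations``) is reported through ``converged=False``, never
    silently.
    """
    config = config or MCMCConfig()
    y_obs = record.y
    obs_mask = record.obs_mask & np.isfinite(y_obs)
    t_len = y_obs.shape[0]

    # initial fill for missing entries: linear interpolation per series
    y_fill = y_obs.copy()
    idx = np.arange(t_len)
    for j in range(2):
        ok = obs_mask[:, j]
        y_fill[~ok, j] = np.interp(idx[~ok], idx[ok], y_obs[ok, j])
    missing_ts = np.flatnonzero(~obs_mask.all(axis=1))

    both = obs_mask.all(axis=1)
    ybar = y_obs[both].mean(axis=0)
    ycov = np.cov(y_obs[both].T) + 1e-8 * np.eye(2)

    root = np.random.SeedSequence(config.seed)
    states = []
    rngs = []
    for c, ss in enumerate(root.spawn(config.n_chains)):
        rng = np.random.default_rng(ss)
        mu0 = ybar + 2.0 * np.sqrt(np.diag(ycov)) * rng.standard_normal(2)
        sigma0 = ycov * np.exp(rng.uniform(-0.7, 0.7))
        states.append(
            {"y": y_fill.copy(), "mu": mu0, "B": np.zeros((2, 2)), "Sigma": sigma0}
        )
        rngs.append(rng)

    n_params = len(PARAM_NAMES)
    draws = np.empty((config.n_chains, config.max_iterations, n_params))
    n_used = config.max_iterations
    converged = False
    for it in range(config.max_iterations):
        for c in range(config.n_chains):
            _gibbs_step(states[c], rngs[c], obs_mask, missing_ts, config)
            draws[c, it] = _extract_params(states[c])
        done = it + 1
        if done >= config.min_iterations and done % config.check_interval == 0:
            res = psr(draws[:, :done, :])
            if np.all(res.values < config.psr_threshold):
                n_used = done
                converged = True
                break
    else:
        res = psr(draws[:, : config.max_iterations, :])
        converged = bool(np.all(res.values < config.psr_threshold))

    burn = int(config.burn_in_fraction * n_used)
    kept = draws[:, burn:n_used, :]
    pooled = kept.reshape(-1, n_params)

    admissible = _admissible_mask(pooled)
    discarded_fraction = float(1.0 - admissible.mean())
    use = pooled[admissible] if admissible.any() else pooled

    alpha = (1.0 - config.cri_level) / 2.0
    lo = np.percentile(use, 100 * alpha, axis=0)
    hi = np.percentile(use, 100 * (1 - alpha), axis=0)
    med = np.median(use, axis=0)
    params = {
        name: ParamSummary(
            median=float(med[k]),
            cri_low=float(lo[k]),
            cri_high=float(hi[k]),
            psr=float(res.values[k]),
        )
        for k, name in enumerate(PARAM_NAMES)
    }
    return VARPosterior(
        dyad_id=record.dyad_id,
        task=record.task,
        params=params,
        discarded_fraction=discarded_fraction,
        n_iterations_used=n_used,
        converged=converged,
        cri_level=config.cri_level,
        degenerate_params=tuple(
            name for k, name in enumerate(PARAM_NAMES) if res.degenerate[k]
        ),
        draws=kept if config.keep_draws else None,
    )


def _call_direction(summary: ParamSummary) -> str:
    if summary.cri_low > 0.0:
        return "positive"
    if summary.cri_high < 0.0:
        return "negative"
    return "null"  # an endpoint exactly at zero counts as containing zero


def classify_synchrony(posterior: VARPosterior) -> SynchronyCall:
    """Credible-interval rule: non-null iff the CrI excludes zero."""
    return SynchronyCall(
        dyad_id=posterior.dyad_id,
        task=posterior.task,
        parent_driven=_call_direction(posterior.params["beta_parent_to_child"]),
        child_driven=_call_direction(posterior.params["beta_child_to_parent"]),
        converged=posterior.converged,
    )
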