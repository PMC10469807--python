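"""Markov chain Monte Carlo samplers for two-arm evidence networks.

Two likelihoods are supported, both expressed through a trial-by-parameter
design matrix ``X`` so that the consistency model, the unrelated-mean-effects
(UME) model and node-split models all reuse the same machinery:

* contrast level: ``y_i ~ Normal(delta_i, s_i^2)``
* arm level:      ``r_ik ~ Binomial(n_ik, p_ik)`` with
  ``logit p_i,ctl = mu_i`` and ``logit p_i,exp = mu_i + delta_i``

Under the random-effects model ``delta_i ~ Normal((X beta)_i, tau^2)``;
under the fixed-effect model ``delta_i = (X beta)_i`` exactly.  Priors are
vague: ``beta_k ~ Normal(0, prior_sd^2)``, ``mu_i ~ Normal(0, prior_sd^2)``
and ``tau ~ Uniform(0, tau_upper)``.

The scheme is Metropolis-within-Gibbs: normal full conditionals (the trial
effects under the contrast likelihood, and ``beta`` given the trial
effects) are drawn exactly; the non-conjugate blocks (``mu`` and ``delta``
under the binomial likelihood, and ``tau``) use per-parameter random-walk
Metropolis steps whose proposal scales adapt during burn-in only.  All
chains advance in lock-step through vectorized updates, and every random
draw comes from one seeded generator in a fixed order (trial effects,
baselines, basic effects, heterogeneity SD within each sweep), so a given
seed reproduces the draws bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["McmcSettings", "RawDraws", "sample_contrast", "sample_binary"]

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk proposals


@dataclass(frozen=True)
class McmcSettings:
    """Sampler run lengths; defaults follow common NMA practice."""

    chains: int = 4
    burn_in: int = 10_000
    kept_iterations: int = 50_000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.burn_in <= 0 or self.kept_iterations <= 0 or self.thin <= 0:
            raise ValueError("burn_in, kept_iterations and thin must be positive")

    @property
    def draws_per_chain(self) -> int:
        return self.kept_iterations // self.thin


@dataclass
class RawDraws:
    """Posterior draws, shaped (chains, draws_per_chain, ...)."""

    beta: np.ndarray  # (C, D, P) basic parameters
    tau: np.ndarray | None  # (C, D); None for fixed-effect fits
    delta: np.ndarray  # (C, D, N) per-trial effects
    mu: np.ndarray | None  # (C, D, N) per-trial baselines (binary only)
    deviance: np.ndarray  # (C, D) residual deviance


def _chain_offsets(chains: int) -> np.ndarray:
    """Overdispersed starting offsets for the basic parameters.

    Four chains start at (-2, -0.5, +0.5, +2) x prior_sd x 0.1; other chain
    counts interpolate the same +-2 span.
    """
    if chains == 4:
        return np.array([-2.0, -0.5, 0.5, 2.0])
    return np.linspace(-2.0, 2.0, chains)


def _adapt(scale: np.ndarray, accepted: np.ndarray) -> None:
    rate = accepted / _ADAPT_WINDOW
    scale *= np.exp(0.3 * (rate - _TARGET_ACCEPT))
    np.clip(scale, 1e-4, 50.0, out=scale)
    accepted[...] = 0.0


def _sample_beta_conjugate(
    rng: np.random.Generator,
    delta: np.ndarray,
    X: np.ndarray,
    tau2: np.ndarray,
    prior_prec: float,
) -> np.ndarray:
    """Exact draw of beta | delta, tau for delta ~ N(X beta, tau^2 I)."""
    C, P = delta.shape[0], X.shape[1]
    XtX = X.T @ X  # (P, P)
    prec = XtX[None, :, :] / tau2[:, None, None] + prior_prec * np.eye(P)[None, :, :]
    b = (delta @ X) / tau2[:, None]  # (C, P)
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, b[:, :, None])[:, :, 0]
    z = rng.standard_normal((C, P))
    noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
    return mean + noise


def _tau_step(
    rng: np.random.Generator,
    tau: np.ndarray,
    resid2: np.ndarray,
    n_eff: int,
    tau_upper: float,
    scale: np.ndarray,
    accepted: np.ndarray,
) -> np.ndarray:
    """Random-walk Metropolis on tau with target prod_i N(delta_i; m_i, tau^2)."""
    prop = tau + scale * rng.standard_normal(tau.shape)
    log_u = np.log(rng.uniform(size=tau.shape))
    valid = (prop > 0) & (prop < tau_upper)
    safe = np.where(valid, prop, tau)
    logp_cur = -n_eff * np.log(tau) - resid2 / (2 * tau**2)
    logp_prop = -n_eff * np.log(safe) - resid2 / (2 * safe**2)
    accept = valid & (log_u < logp_prop - logp_cur)
    accepted += accept
    return np.where(accept, prop, tau)


def sample_contrast(
    y: np.ndarray,
    s: np.ndarray,
    X: np.ndarray,
    *,
    random_effects: bool = True,
    tau_upper: float = 2.0,
    prior_sd: float = 10.0,
    settings: McmcSettings = McmcSettings(),
) -> RawDraws:
    """Sample the normal-likelihood (log hazard ratio) model."""
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    X = np.asarray(X, float)
    N, P = X.shape
    C = settings.chains
    rng = np.random.default_rng(settings.seed)
    prior_prec = 1.0 / prior_sd**2
    inv_s2 = 1.0 / s**2

    beta = np.tile(_chain_offsets(C)[:, None] * prior_sd * 0.1, (1, P))
    tau = tau_upper * (np.arange(C) + 1.0) / (C + 1.0)
    delta = np.tile(y, (C, 1))

    if not random_effects:
        # beta | y is exactly multivariate normal: independent draws each sweep
        prec = X.T @ (X * inv_s2[:, None]) + prior_prec * np.eye(P)
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ (y * inv_s2))
        Lt_inv = np.linalg.inv(L.T)

    tau_scale = np.full(C, 0.1 * tau_upper)
    tau_acc = np.zeros(C)

    D = settings.draws_per_chain
    out_beta = np.empty((C, D, P))
    out_tau = np.empty((C, D)) if random_effects else None
    out_delta = np.empty((C, D, N))
    out_dev = np.empty((C, D))

    total = settings.burn_in + settings.kept_iterations
    k = 0
    for it in range(total):
        if random_effects:
            m = beta @ X.T  # (C, N)
            prec_d = inv_s2[None, :] + 1.0 / tau[:, None] ** 2
            mean_d = (y * inv_s2 + m / tau[:, None] ** 2) / prec_d
            delta = mean_d + rng.standard_normal((C, N)) / np.sqrt(prec_d)
            beta = _sample_beta_conjugate(rng, delta, X, tau**2, prior_prec)
            m = beta @ X.T
            resid2 = np.sum((delta - m) ** 2, axis=1)
            tau = _tau_step(rng, tau, resid2, N, tau_upper, tau_scale, tau_acc)
            if it < settings.burn_in and (it + 1) % _ADAPT_WINDOW == 0:
                _adapt(tau_scale, tau_acc)
        else:
            z = rng.standard_normal((C, P))
            beta = mean[None, :] + z @ Lt_inv.T
            delta = beta @ X.T

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            out_beta[:, k] = beta
            if random_effects:
                out_tau[:, k] = tau
            out_delta[:, k] = delta
            out_dev[:, k] = np.sum((y - delta) ** 2 * inv_s2, axis=1)
            k += 1

    return RawDraws(beta=out_beta, tau=out_tau, delta=out_delta, mu=None, deviance=out_dev)


def _binom_loglik(theta: np.ndarray, r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binomial log likelihood in the logit parameter, up to constants."""
    return r * theta - n * np.logaddexp(0.0, theta)


def binomial_residual_deviance(
    r: np.ndarray, n: np.ndarray, p: np.ndarray, axis=-1
) -> np.ndarray:
    """Residual deviance of binomial arms against fitted probabilities."""
    r = np.asarray(r, float)
    n = np.asarray(n, float)
    fitted = n * p
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / fitted), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - fitted)), 0.0)
    return 2.0 * np.sum(t1 + t2, axis=axis)


def sample_binary(
    r1: np.ndarray,
    n1: np.ndarray,
    r0: np.ndarray,
    n0: np.ndarray,
    X: np.ndarray,
    *,
    random_effects: bool = True,
    tau_upper: float = 5.0,
    prior_sd: float = 10.0,
    baseline_prior_sd: float = 10.0,
    settings: McmcSettings = McmcSettings(),
) -> RawDraws:
    """Sample the binomial-logit model on arm-level counts.

    Arm 1 is the experimental arm (baseline plus trial effect), arm 0 the
    control arm (baseline only).
    """
    r1 = np.asarray(r1, float)
    n1 = np.asarray(n1, float)
    r0 = np.asarray(r0, float)
    n0 = np.asarray(n0, float)
    X = np.asarray(X, float)
    N, P = X.shape
    C = settings.chains
    rng = np.random.default_rng(settings.seed)
    prior_prec = 1.0 / prior_sd**2
    base_prec = 1.0 / baseline_prior_sd**2

    def emp_logit(r, n):
        p = np.clip((r + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
        return np.log(p / (1 - p))

    mu = np.tile(emp_logit(r0, n0), (C, 1))
    delta = np.tile(emp_logit(r1, n1) - emp_logit(r0, n0), (C, 1))
    beta = np.tile(_chain_offsets(C)[:, None] * prior_sd * 0.1, (1, P))
    tau = tau_upper * (np.arange(C) + 1.0) / (C + 1.0)

    mu_scale = np.full((C, N), 0.4)
    mu_acc = np.zeros((C, N))
    d_scale = np.full((C, N), 0.4)
    d_acc = np.zeros((C, N))
    beta_scale = np.full((C, P), 0.4)
    beta_acc = np.zeros((C, P))
    tau_scale = np.full(C, 0.1 * tau_upper)
    tau_acc = np.zeros(C)

    D = settings.draws_per_chain
    out_beta = np.empty((C, D, P))
    out_tau = np.empty((C, D)) if random_effects else None
    out_delta = np.empty((C, D, N))
    out_mu = np.empty((C, D, N))
    out_dev = np.empty((C, D))

    total = settings.burn_in + settings.kept_iterations
    k = 0
    for it in range(total):
        m = beta @ X.T  # (C, N)
        if not random_effects:
            delta = m

        # baselines: likelihood of both arms factorizes across trials
        prop = mu + mu_scale * rng.standard_normal((C, N))
        log_u = np.log(rng.uniform(size=(C, N)))
        ll_cur = (
            _binom_loglik(mu, r0, n0)
            + _binom_loglik(mu + delta, r1, n1)
            - base_prec * mu**2 / 2.0
        )
        ll_prop = (
            _binom_loglik(prop, r0, n0)
            + _binom_loglik(prop + delta, r1, n1)
            - base_prec * prop**2 / 2.0
        )
        accept = log_u < ll_prop - ll_cur
        mu = np.where(accept, prop, mu)
        mu_acc += accept

        if random_effects:
            # trial effects: experimental-arm likelihood x normal prior
            prop = delta + d_scale * rng.standard_normal((C, N))
            log_u = np.log(rng.uniform(size=(C, N)))
            tau2 = tau[:, None] ** 2
            ll_cur = _binom_loglik(mu + delta, r1, n1) - (delta - m) ** 2 / (2 * tau2)
            ll_prop = _binom_loglik(mu + prop, r1, n1) - (prop - m) ** 2 / (2 * tau2)
            accept = log_u < ll_prop - ll_cur
            delta = np.where(accept, prop, delta)
            d_acc += accept

            beta = _sample_beta_conjugate(rng, delta, X, tau**2, prior_prec)
            resid2 = np.sum((delta - beta @ X.T) ** 2, axis=1)
            tau = _tau_step(rng, tau, resid2, N, tau_upper, tau_scale, tau_acc)
        else:
            # basic parameters one coordinate at a time (non-conjugate)
            for p_idx in range(P):
                step = beta_scale[:, p_idx] * rng.standard_normal(C)
                log_u = np.log(rng.uniform(size=C))
                beta_prop = beta.copy()
                beta_prop[:, p_idx] += step
                m_prop = beta_prop @ X.T
                ll_cur = (
                    np.sum(_binom_loglik(mu + m, r1, n1), axis=1)
                    - prior_prec * beta[:, p_idx] ** 2 / 2.0
                )
                ll_prop = (
                    np.sum(_binom_loglik(mu + m_prop, r1, n1), axis=1)
                    - prior_prec * beta_prop[:, p_idx] ** 2 / 2.0
                )
                accept = log_u < ll_prop - ll_cur
                beta = np.where(accept[:, None], beta_prop, beta)
                m = np.where(accept[:, None], m_prop, m)
                beta_acc[:, p_idx] += accept
            delta = m

        if it < settings.burn_in and (it + 1) % _ADAPT_WINDOW == 0:
            _adapt(mu_scale, mu_acc)
            if random_effects:
                _adapt(d_scale, d_acc)
                _adapt(tau_scale, tau_acc)
            else:
                _adapt(beta_scale, beta_acc)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            out_beta[:, k] = beta
            if random_effects:
                out_tau[:, k] = tau
            out_delta[:, k] = delta
            out_mu[:, k] = mu
            p0 = 1.0 / (1.0 + np.exp(-mu))
            p1 = 1.0 / (1.0 + np.exp(-(mu + delta)))
            out_dev[:, k] = binomial_residual_deviance(
                r0, n0, p0
            ) + binomial_residual_deviance(r1, n1, p1)
            k += 1

    return RawDraws(
        beta=out_beta, tau=out_tau, delta=out_delta, mu=out_mu, deviance=out_dev
    )
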