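"""Bayesian network meta-analysis: model specification, fitting, summaries.

The consistency model expresses every trial contrast through basic
parameters ``d_k`` (log HR or log OR of treatment k versus the reference,
with ``d_reference = 0``), so consistency relations ``d_AB + d_BC = d_AC``
hold exactly in every draw.  The unrelated-mean-effects (UME) model used
as the global-inconsistency benchmark instead gives every observed
comparison its own free parameter; both are linear designs over the same
samplers in :mod:`alknma.mcmc`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .mcmc import (
    McmcSettings,
    RawDraws,
    binomial_residual_deviance,
    sample_binary,
    sample_contrast,
)
from .network import EvidenceNetwork

__all__ = [
    "NmaModelSpec",
    "PosteriorSamples",
    "LeagueTable",
    "ConvergenceReport",
    "ConvergenceWarning",
    "fit_nma",
    "league_table",
    "gelman_rubin",
    "compute_dic",
]

PSRF_THRESHOLD = 1.05


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class NmaModelSpec:
    """Model and sampler configuration for one NMA fit.

    ``tau_upper`` is the upper bound of the uniform prior on the
    between-trial SD; when ``None`` it defaults per outcome type (2 on the
    log-HR scale for contrast data, 5 on the log-OR scale for binary data).
    """

    effect_model: str = "random"  # 'random' | 'fixed'
    consistency: str = "consistent"  # 'consistent' | 'ume_inconsistent'
    reference: str | None = None  # default: first treatment of the network
    effect_prior_sd: float = 10.0
    baseline_prior_sd: float = 10.0
    tau_upper: float | None = None
    chains: int = 4
    burn_in: int = 10_000
    kept_iterations: int = 50_000
    thin: int = 2
    seed: int = 20230619

    def __post_init__(self) -> None:
        if self.effect_model not in ("random", "fixed"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")
        if self.consistency not in ("consistent", "ume_inconsistent"):
            raise ValueError(f"unknown consistency {self.consistency!r}")

    def mcmc_settings(self) -> McmcSettings:
        return McmcSettings(
            chains=self.chains,
            burn_in=self.burn_in,
            kept_iterations=self.kept_iterations,
            thin=self.thin,
            seed=self.seed,
        )

    def resolved_tau_upper(self, data_kind: str) -> float:
        if self.tau_upper is not None:
            return self.tau_upper
        return 2.0 if data_kind == "contrast_loghr" else 5.0

    def with_(self, **kw) -> "NmaModelSpec":
        return NmaModelSpec(**{**self.__dict__, **kw})


@dataclass(frozen=True)
class ConvergenceReport:
    psrf: dict  # parameter -> split-chain PSRF
    ess: dict  # parameter -> effective sample size
    passed: bool

    @property
    def worst(self) -> tuple[str, float]:
        name = max(self.psrf, key=self.psrf.get)
        return name, self.psrf[name]


@dataclass
class PosteriorSamples:
    """Posterior draws of one fit, with the design metadata to read them.

    ``param_names`` labels the columns of ``raw.beta``: treatment ids for a
    consistency fit, edge labels for a UME fit.
    """

    param_names: tuple[str, ...]
    treatments: tuple[str, ...]
    reference: str | None
    trial_ids: tuple[str, ...]
    raw: RawDraws
    spec: NmaModelSpec
    data_kind: str
    parameterization: str = "consistency"  # 'consistency' | 'ume' | 'nodesplit'
    convergence: ConvergenceReport | None = None

    @property
    def n_draws(self) -> int:
        c, d, _ = self.raw.beta.shape
        return c * d

    def basic_effect_draws(self, treatment: str) -> np.ndarray:
        """Flattened draws of d_treatment (zeros for the reference)."""
        if self.parameterization != "consistency":
            raise ValueError("basic effects only defined for consistency fits")
        if treatment == self.reference:
            return np.zeros(self.n_draws)
        idx = self.param_names.index(treatment)
        return self.raw.beta[:, :, idx].reshape(-1)

    def contrast_draws(self, treat_a: str, treat_b: str) -> np.ndarray:
        """Draws of d_a - d_b: the log relative effect of a versus b."""
        return self.basic_effect_draws(treat_a) - self.basic_effect_draws(treat_b)

    def d_matrix(self) -> np.ndarray:
        """(n_draws, K) matrix of basic effects in treatment order."""
        cols = [self.basic_effect_draws(t) for t in self.treatments]
        return np.column_stack(cols)

    @property
    def heterogeneity_sd(self) -> np.ndarray | None:
        return None if self.raw.tau is None else self.raw.tau.reshape(-1)

    def to_draws_frame(self) -> pd.DataFrame:
        """Flat (chain, iteration, parameter, value) export."""
        C, D, P = self.raw.beta.shape
        frames = []
        for p_idx, name in enumerate(self.param_names):
            for c in range(C):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(D),
                            "parameter": f"d.{name}",
                            "value": self.raw.beta[c, :, p_idx],
                        }
                    )
                )
        if self.raw.tau is not None:
            for c in range(C):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(D),
                            "parameter": "tau",
                            "value": self.raw.tau[c],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Design matrices and data assembly
# ---------------------------------------------------------------------------


def consistency_design(
    network: EvidenceNetwork, reference: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Rows: trials; columns: non-reference treatments (+1 alt, -1 ref)."""
    params = [t for t in network.treatment_ids if t != reference]
    col = {t: i for i, t in enumerate(params)}
    contrasts = network.trial_contrasts()
    X = np.zeros((len(contrasts), len(params)))
    trials = []
    for i, (trial, ref, alt) in enumerate(contrasts):
        trials.append(trial)
        if alt != reference:
            X[i, col[alt]] += 1.0
        if ref != reference:
            X[i, col[ref]] -= 1.0
    return X, params, trials


def ume_design(network: EvidenceNetwork) -> tuple[np.ndarray, list[str], list[str]]:
    """Rows: trials; columns: one free parameter per observed comparison.

    Each edge is oriented as in the first trial observed on it; later
    trials with the opposite orientation load with -1.
    """
    contrasts = network.trial_contrasts()
    edge_orient: dict[frozenset, tuple[str, str]] = {}
    params: list[str] = []
    for _, ref, alt in contrasts:
        key = frozenset((ref, alt))
        if key not in edge_orient:
            edge_orient[key] = (ref, alt)
            params.append(f"{alt}.vs.{ref}")
    keys = list(edge_orient)
    X = np.zeros((len(contrasts), len(keys)))
    trials = []
    for i, (trial, ref, alt) in enumerate(contrasts):
        trials.append(trial)
        key = frozenset((ref, alt))
        j = keys.index(key)
        X[i, j] = 1.0 if edge_orient[key] == (ref, alt) else -1.0
    return X, params, trials


def contrast_arrays(network: EvidenceNetwork) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([o.log_effect for o in network.observations])
    s = np.array([o.se for o in network.observations])
    return y, s


def binary_arrays(
    network: EvidenceNetwork, trial_order: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arms = network.arms_by_trial()
    r1 = np.array([arms[t][0].events for t in trial_order], float)
    n1 = np.array([arms[t][0].n for t in trial_order], float)
    r0 = np.array([arms[t][1].events for t in trial_order], float)
    n0 = np.array([arms[t][1].n for t in trial_order], float)
    return r1, n1, r0, n0


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _sample_design(
    network: EvidenceNetwork,
    spec: NmaModelSpec,
    X: np.ndarray,
    trial_order: list[str],
) -> RawDraws:
    kind = network.outcome.data_kind
    settings = spec.mcmc_settings()
    tau_upper = spec.resolved_tau_upper(kind)
    random_effects = spec.effect_model == "random"
    if kind == "contrast_loghr":
        y, s = contrast_arrays(network)
        return sample_contrast(
            y,
            s,
            X,
            random_effects=random_effects,
            tau_upper=tau_upper,
            prior_sd=spec.effect_prior_sd,
            settings=settings,
        )
    r1, n1, r0, n0 = binary_arrays(network, trial_order)
    return sample_binary(
        r1,
        n1,
        r0,
        n0,
        X,
        random_effects=random_effects,
        tau_upper=tau_upper,
        prior_sd=spec.effect_prior_sd,
        baseline_prior_sd=spec.baseline_prior_sd,
        settings=settings,
    )


def fit_nma(
    network: EvidenceNetwork,
    spec: NmaModelSpec = NmaModelSpec(),
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Fit the Bayesian NMA and return posterior samples.

    A fit whose split-chain PSRF exceeds 1.05 on any parameter is returned
    flagged (``convergence.passed`` False) with a :class:`ConvergenceWarning`,
    never silently accepted.
    """
    reference = spec.reference or network.treatment_ids[0]
    if reference not in network.treatment_ids:
        raise KeyError(f"reference treatment {reference!r} not in network")
    if spec.consistency == "ume_inconsistent":
        X, params, trials = ume_design(network)
        parameterization = "ume"
        reference_out = None
    else:
        X, params, trials = consistency_design(network, reference)
        parameterization = "consistency"
        reference_out = reference
    raw = _sample_design(network, spec, X, trials)
    samples = PosteriorSamples(
        param_names=tuple(params),
        treatments=network.treatment_ids,
        reference=reference_out,
        trial_ids=tuple(trials),
        raw=raw,
        spec=spec,
        data_kind=network.outcome.data_kind,
        parameterization=parameterization,
    )
    if check_convergence:
        report = gelman_rubin(samples)
        samples.convergence = report
        if not report.passed:
            name, value = report.worst
            warnings.warn(
                f"MCMC convergence not reached: PSRF({name}) = {value:.3f}",
                ConvergenceWarning,
                stacklevel=2,
            )
    return samples


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeagueTable:
    """All pairwise relative effects on the ratio scale.

    Cell (row i, column j) summarizes exp(d_j - d_i): the effect of the
    *column* treatment relative to the *row* treatment.  Point estimates
    are posterior medians computed on the log scale, so the reciprocal
    identity ``entry(a, b) = 1 / entry(b, a)`` is exact.
    """

    treatments: tuple[str, ...]
    median: np.ndarray  # (K, K)
    low: np.ndarray
    high: np.ndarray
    bayes_p: np.ndarray
    scale: str  # 'hr' | 'or'

    def entry(self, column: str, row: str) -> dict:
        i = self.treatments.index(row)
        j = self.treatments.index(column)
        return {
            "median": self.median[i, j],
            "ci95": (self.low[i, j], self.high[i, j]),
            "bayes_p": self.bayes_p[i, j],
        }

    def significant(self, column: str, row: str, alpha: float = 0.05) -> bool:
        return self.entry(column, row)["bayes_p"] < alpha

    def to_dataframe(self) -> pd.DataFrame:
        k = len(self.treatments)
        cells = []
        for i in range(k):
            row = []
            for j in range(k):
                if i == j:
                    row.append(self.treatments[i])
                else:
                    row.append(
                        f"{self.median[i, j]:.2f} ({self.low[i, j]:.2f}, {self.high[i, j]:.2f})"
                    )
            cells.append(row)
        return pd.DataFrame(cells, index=self.treatments, columns=self.treatments)


def bayesian_p(diff_draws: np.ndarray) -> float:
    """Two-sided posterior tail probability: 2 * min(Pr(>0), Pr(<0))."""
    p_pos = float(np.mean(diff_draws > 0))
    p_neg = float(np.mean(diff_draws < 0))
    return min(1.0, 2.0 * min(p_pos, p_neg))


def league_table(samples: PosteriorSamples, scale: str | None = None) -> LeagueTable:
    """League table of posterior medians and 95% credible intervals."""
    if scale is None:
        scale = "hr" if samples.data_kind == "contrast_loghr" else "or"
    treats = samples.treatments
    k = len(treats)
    d = samples.d_matrix()  # (n, K)
    median = np.ones((k, k))
    low = np.ones((k, k))
    high = np.ones((k, k))
    p = np.ones((k, k))
    for i in range(k):  # row
        for j in range(k):  # column
            if i == j:
                continue
            diff = d[:, j] - d[:, i]
            q = np.quantile(diff, [0.025, 0.5, 0.975])
            low[i, j], median[i, j], high[i, j] = np.exp(q)
            p[i, j] = bayesian_p(diff)
    return LeagueTable(
        treatments=treats, median=median, low=low, high=high, bayes_p=p, scale=scale
    )


def _as_arviz(samples: PosteriorSamples) -> az.InferenceData:
    data = {
        f"d.{name}": samples.raw.beta[:, :, i]
        for i, name in enumerate(samples.param_names)
    }
    if samples.raw.tau is not None:
        data["tau"] = samples.raw.tau
    return az.convert_to_inference_data(data)


def gelman_rubin(samples: PosteriorSamples) -> ConvergenceReport:
    """Split-chain potential scale reduction factors and effective sizes."""
    if samples.raw.beta.shape[0] < 2:
        raise ValueError("need at least 2 chains for the PSRF")
    idata = _as_arviz(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata, method="split")
        ess = az.ess(idata)
    psrf = {str(k): float(rhat[k].values) for k in rhat.data_vars}
    ess_d = {str(k): float(ess[k].values) for k in ess.data_vars}
    passed = all(np.isfinite(v) and v < PSRF_THRESHOLD for v in psrf.values())
    return ConvergenceReport(psrf=psrf, ess=ess_d, passed=passed)


def compute_dic(
    samples: PosteriorSamples, network: EvidenceNetwork
) -> tuple[float, float, float]:
    """Deviance information criterion from the recorded deviance trace.

    Returns (Dbar, pD, DIC) with Dbar the posterior mean residual deviance,
    pD = Dbar - D(posterior means of the trial-level parameters), and
    DIC = Dbar + pD.
    """
    dev = samples.raw.deviance
    dbar = float(dev.mean())
    delta_hat = samples.raw.delta.mean(axis=(0, 1))
    if network.outcome.data_kind == "contrast_loghr":
        y, s = contrast_arrays(network)
        d_hat = float(np.sum((y - delta_hat) ** 2 / s**2))
    else:
        mu_hat = samples.raw.mu.mean(axis=(0, 1))
        r1, n1, r0, n0 = binary_arrays(network, list(samples.trial_ids))
        p0 = 1.0 / (1.0 + np.exp(-mu_hat))
        p1 = 1.0 / (1.0 + np.exp(-(mu_hat + delta_hat)))
        d_hat = float(
            binomial_residual_deviance(r0, n0, p0)
            + binomial_residual_deviance(r1, n1, p1)
        )
    pd_ = dbar - d_hat
    return dbar, pd_, dbar + pd_
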