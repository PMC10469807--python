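"""Frequentist pairwise meta-analysis of direct comparisons.

Fixed-effect (inverse-variance) and DerSimonian-Laird random-effects
pooling on the log scale, Cochran's Q, the I^2 statistic, and per-trial
odds ratios for binary arm data with the Haldane-Anscombe continuity
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .network import EvidenceNetwork, Z_95

__all__ = [
    "PairwiseResult",
    "ZeroInformationTrial",
    "trial_log_or",
    "pool_fixed",
    "pool_dersimonian_laird",
    "i_squared",
    "direct_comparisons",
]


@dataclass(frozen=True)
class PairwiseResult:
    """Pooled estimate of one direct comparison on the log scale."""

    comparison: tuple[str, str]  # (ref, alt); effect is alt vs ref
    model: str  # 'fixed' | 'random'
    pooled_log_effect: float
    pooled_se: float
    ci95: tuple[float, float]
    Q: float
    df: int
    i_squared: float
    tau_squared: float
    n_studies: int
    heterogeneity_estimable: bool = True

    @property
    def pooled_ratio(self) -> float:
        """Pooled effect back on the ratio (HR/OR) scale."""
        return math.exp(self.pooled_log_effect)

    @property
    def ci95_ratio(self) -> tuple[float, float]:
        return (math.exp(self.ci95[0]), math.exp(self.ci95[1]))


class ZeroInformationTrial(ValueError):
    """Both arms all-events or both no-events: the 2x2 table carries no contrast."""


def trial_log_or(r1: int, n1: int, r0: int, n0: int) -> tuple[float, float]:
    """Log odds ratio (arm 1 vs arm 0) and its SE from a 2x2 table.

    If any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe).
    Double-zero or double-full tables raise :class:`ZeroInformationTrial`.
    """
    if not (0 <= r1 <= n1 and 0 <= r0 <= n0):
        raise ValueError("event counts must satisfy 0 <= r <= n")
    if (r1 == 0 and r0 == 0) or (r1 == n1 and r0 == n0):
        raise ZeroInformationTrial(
            f"table ({r1}/{n1}, {r0}/{n0}) has no between-arm information"
        )
    a, b = float(r1), float(n1 - r1)
    c, d = float(r0), float(n0 - r0)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def _assemble(effects) -> tuple[np.ndarray, np.ndarray]:
    eff = [(float(y), float(s)) for y, s in effects]
    if not eff:
        raise ValueError("no studies to pool")
    y = np.array([e[0] for e in eff])
    s = np.array([e[1] for e in eff])
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    return y, s


def i_squared(Q: float, df: int) -> float:
    """I^2 heterogeneity percentage: 100 * max(0, (Q - df) / Q)."""
    if Q < 0 or df < 0:
        raise ValueError("Q and df must be non-negative")
    if Q == 0 or df == 0:
        return 0.0
    return 100.0 * max(0.0, (Q - df) / Q)


def pool_fixed(effects, comparison: tuple[str, str] = ("ref", "alt")) -> PairwiseResult:
    """Inverse-variance fixed-effect pooling of (log_effect, se) pairs."""
    y, s = _assemble(effects)
    w = 1.0 / s**2
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (y - pooled) ** 2))
    df = len(y) - 1
    return PairwiseResult(
        comparison=comparison,
        model="fixed",
        pooled_log_effect=pooled,
        pooled_se=pooled_se,
        ci95=(pooled - Z_95 * pooled_se, pooled + Z_95 * pooled_se),
        Q=Q,
        df=df,
        i_squared=i_squared(Q, df),
        tau_squared=0.0,
        n_studies=len(y),
        heterogeneity_estimable=df > 0,
    )


def pool_dersimonian_laird(
    effects, comparison: tuple[str, str] = ("ref", "alt")
) -> PairwiseResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) from the
    fixed-effect weights, then re-pool with weights 1/(se^2 + tau^2).
    A single study degenerates to the fixed result with tau^2 = 0.
    """
    y, s = _assemble(effects)
    fixed = pool_fixed(effects, comparison)
    if len(y) == 1:
        return PairwiseResult(
            **{**fixed.__dict__, "model": "random", "heterogeneity_estimable": False}
        )
    w = 1.0 / s**2
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (fixed.Q - fixed.df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    return PairwiseResult(
        comparison=comparison,
        model="random",
        pooled_log_effect=pooled,
        pooled_se=pooled_se,
        ci95=(pooled - Z_95 * pooled_se, pooled + Z_95 * pooled_se),
        Q=fixed.Q,
        df=fixed.df,
        i_squared=fixed.i_squared,
        tau_squared=tau2,
        n_studies=len(y),
    )


def comparison_effects(network: EvidenceNetwork) -> dict[tuple[str, str], list]:
    """Per-edge study effects (alt vs ref, log scale) with trial labels.

    Binary trials yield log odds ratios; double-zero / double-full trials
    are excluded with a warning, per the zero-information rule.
    """
    out: dict[tuple[str, str], list] = {}
    if network.outcome.data_kind == "contrast_loghr":
        for o in network.observations:
            out.setdefault((o.treat_ref, o.treat_alt), []).append(
                (o.trial_id, o.log_effect, o.se)
            )
        return out
    for trial, (exp_arm, ctl_arm) in network.arms_by_trial().items():
        try:
            log_or, se = trial_log_or(exp_arm.events, exp_arm.n, ctl_arm.events, ctl_arm.n)
        except ZeroInformationTrial:
            warnings.warn(
                f"trial {trial} excluded from pairwise pooling: no between-arm information",
                stacklevel=2,
            )
            continue
        out.setdefault((ctl_arm.treatment, exp_arm.treatment), []).append(
            (trial, log_or, se)
        )
    return out


def direct_comparisons(
    network: EvidenceNetwork, model: str = "random"
) -> dict[tuple[str, str], PairwiseResult]:
    """Pool every direct comparison of a network with one model."""
    pool = pool_dersimonian_laird if model == "random" else pool_fixed
    return {
        pair: pool([(y, s) for _, y, s in studies], comparison=pair)
        for pair, studies in comparison_effects(network).items()
    }
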