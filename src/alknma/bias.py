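"""Publication-bias and small-study-effect diagnostics.

Comparison-adjusted funnel data (each study centered on its own direct
comparison's pooled effect), contour-enhanced significance boundaries,
Egger's weighted regression test, Begg's rank-correlation test, and the
Duval-Tweedie trim-and-fill correction with the rank-based L0 and R0
estimators of the number of suppressed studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import EvidenceNetwork
from .pairwise import comparison_effects, pool_dersimonian_laird, pool_fixed

__all__ = [
    "FunnelPoint",
    "EggerResult",
    "BeggResult",
    "TrimFillResult",
    "comparison_adjusted_funnel",
    "contour_rays",
    "egger_test",
    "begg_test",
    "trim_and_fill",
    "network_effects",
]

CONTOUR_LEVELS = (0.10, 0.05, 0.01)


@dataclass(frozen=True)
class FunnelPoint:
    study: str
    centered_effect: float
    se: float
    comparison: tuple[str, str] = ("", "")
    imputed: bool = False


def network_effects(network: EvidenceNetwork) -> list[tuple[str, float, float]]:
    """All study effects oriented experimental-vs-control, with SEs."""
    out = []
    for studies in comparison_effects(network).values():
        out.extend(studies)
    out.sort(key=lambda t: t[0])
    return out


def comparison_adjusted_funnel(network: EvidenceNetwork) -> list[FunnelPoint]:
    """Funnel points centered per direct comparison's fixed-effect pool."""
    points = []
    for pair, studies in comparison_effects(network).items():
        pooled = pool_fixed([(y, s) for _, y, s in studies], comparison=pair)
        for trial, y, s in studies:
            points.append(
                FunnelPoint(
                    study=trial,
                    centered_effect=y - pooled.pooled_log_effect,
                    se=s,
                    comparison=pair,
                )
            )
    return points


def contour_rays(
    se_max: float, levels: tuple[float, ...] = CONTOUR_LEVELS
) -> pd.DataFrame:
    """Significance-contour boundaries: effect = +-z(p/2) * se rays.

    Long-format table with columns (level, side, se, effect) holding the
    two boundary rays per two-sided level, ready for a plotting layer.
    """
    rows = []
    for level in levels:
        z = stats.norm.ppf(1.0 - level / 2.0)
        for side in (-1.0, 1.0):
            for se in (0.0, se_max):
                rows.append(
                    {"level": level, "side": "left" if side < 0 else "right",
                     "se": se, "effect": side * z * se}
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    p: float
    slope: float
    n: int
    computable: bool = True


def egger_test(effects) -> EggerResult:
    """Egger's regression test for funnel asymmetry.

    Regresses the standard normal deviate y_i/se_i on precision 1/se_i;
    the intercept estimates asymmetry and is tested against zero with a
    two-sided t-test on n - 2 degrees of freedom.
    """
    eff = [(float(y), float(s)) for y, s in effects]
    if len(eff) < 3:
        return EggerResult(math.nan, math.nan, math.nan, math.nan, len(eff), False)
    y = np.array([e[0] for e in eff])
    s = np.array([e[1] for e in eff])
    snd = y / s
    prec = 1.0 / s
    design = np.column_stack([np.ones_like(prec), prec])
    coef, res, *_ = np.linalg.lstsq(design, snd, rcond=None)
    n = len(y)
    resid = snd - design @ coef
    sigma2 = float(resid @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    intercept, slope = coef
    se_int = math.sqrt(cov[0, 0])
    t = intercept / se_int
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return EggerResult(float(intercept), se_int, float(p), float(slope), n)


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    p: float
    n: int
    computable: bool = True


def begg_test(effects) -> BeggResult:
    """Begg-Mazumdar rank correlation between effects and their variances.

    Correlates the variance-stabilized deviates
    (y_i - pooled) / sqrt(se_i^2 - var(pooled)) with se_i^2 using
    Kendall's tau-b (tie-corrected) and its normal-approximation p-value.
    """
    eff = [(float(y), float(s)) for y, s in effects]
    if len(eff) < 3:
        return BeggResult(math.nan, math.nan, len(eff), False)
    y = np.array([e[0] for e in eff])
    s = np.array([e[1] for e in eff])
    pooled = pool_fixed(eff)
    var_pooled = pooled.pooled_se**2
    denom = np.sqrt(np.maximum(s**2 - var_pooled, 1e-12))
    deviate = (y - pooled.pooled_log_effect) / denom
    tau, p = stats.kendalltau(deviate, s**2, method="asymptotic")
    return BeggResult(float(tau), float(p), len(eff))


@dataclass(frozen=True)
class TrimFillResult:
    k0: int
    side: str  # side of the funnel on which studies are imputed
    adjusted_pooled: tuple[float, tuple[float, float]]  # log scale
    original_pooled: tuple[float, tuple[float, float]]
    imputed: tuple = field(default_factory=tuple)  # (effect, se) pairs, log scale
    iterations: int = 0

    @property
    def adjusted_ratio(self) -> tuple[float, tuple[float, float]]:
        est, (lo, hi) = self.adjusted_pooled
        return math.exp(est), (math.exp(lo), math.exp(hi))

    @property
    def original_ratio(self) -> tuple[float, tuple[float, float]]:
        est, (lo, hi) = self.original_pooled
        return math.exp(est), (math.exp(lo), math.exp(hi))


def _k0_estimate(c: np.ndarray, estimator: str) -> int:
    """Rank-based estimate of the suppressed-study count.

    Assumes the canonical orientation: the surplus of extreme studies sits
    on the positive side of the centered effects ``c``.
    """
    n = len(c)
    ranks = stats.rankdata(np.abs(c))
    if estimator == "L0":
        t_pos = float(np.sum(ranks[c > 0]))
        l0 = (4.0 * t_pos - n * (n + 1.0)) / (2.0 * n - 1.0)
        return max(0, int(round(l0)))
    if estimator == "R0":
        neg_ranks = ranks[c < 0]
        gamma = n - (int(np.max(neg_ranks)) if neg_ranks.size else 0)
        return max(0, gamma - 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def trim_and_fill(
    effects,
    estimator: str = "L0",
    side: str | None = None,
    max_iter: int = 50,
) -> TrimFillResult:
    """Duval-Tweedie trim-and-fill correction of a pooled effect set.

    Iteratively: pool the retained studies (fixed effect), center all
    effects, re-estimate the suppressed count k0 by rank statistics, trim
    the k0 most extreme studies on the asymmetric side, and repeat until
    k0 stabilizes.  The k0 trimmed studies are then mirror-imputed about
    the final trimmed pooled estimate and the adjusted summary is the
    DerSimonian-Laird random-effects pool of observed plus imputed studies.

    ``side`` is where studies are presumed missing ('left' or 'right' of
    the funnel); by default it is chosen by the sign of the rank-sum
    asymmetry statistic of the centered effects.
    """
    eff = [(float(y), float(s)) for y, s in effects]
    if len(eff) < 3:
        raise ValueError("trim-and-fill needs at least 3 studies")
    y = np.array([e[0] for e in eff])
    s = np.array([e[1] for e in eff])
    n = len(y)

    if side is None:
        pooled0 = pool_fixed(eff).pooled_log_effect
        c0 = y - pooled0
        ranks = stats.rankdata(np.abs(c0))
        t_pos = float(np.sum(ranks[c0 > 0]))
        # surplus of extreme positive effects => counterparts missing left
        side = "left" if t_pos > n * (n + 1.0) / 4.0 else "right"
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")

    # canonical orientation: surplus on the positive side
    u = y if side == "left" else -y

    k0 = 0
    order = np.argsort(u)  # ascending; extremes of the surplus side last
    for iteration in range(1, max_iter + 1):
        keep = order[: n - k0] if k0 else order
        pooled = pool_fixed(list(zip(u[keep], s[keep]))).pooled_log_effect
        c = u - pooled
        k0_new = min(_k0_estimate(c, estimator), n - 2)
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(
            f"trim-and-fill did not converge in {max_iter} iterations (k0={k0})"
        )

    trimmed_idx = order[n - k0 :] if k0 else np.array([], dtype=int)
    imputed_u = 2.0 * pooled - u[trimmed_idx]
    imputed_s = s[trimmed_idx]

    original = pool_dersimonian_laird(list(zip(y, s)))
    all_u = np.concatenate([u, imputed_u])
    all_s = np.concatenate([s, imputed_s])
    adjusted_u = pool_dersimonian_laird(list(zip(all_u, all_s)))

    flip = 1.0 if side == "left" else -1.0
    adj_est = flip * adjusted_u.pooled_log_effect
    adj_ci = sorted((flip * adjusted_u.ci95[0], flip * adjusted_u.ci95[1]))
    imputed_y = flip * imputed_u

    return TrimFillResult(
        k0=int(k0),
        side=side,
        adjusted_pooled=(adj_est, (adj_ci[0], adj_ci[1])),
        original_pooled=(original.pooled_log_effect, original.ci95),
        imputed=tuple(zip(imputed_y.tolist(), imputed_s.tolist())),
        iterations=iteration,
    )
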