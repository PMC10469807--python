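"""Treatment ranking: rank probabilities, SUCRA, rankogram data.

Per posterior draw the treatments are ordered by their basic effect
(ascending when lower values are clinically better, descending otherwise);
rank 1 is best.  Rank probabilities are the frequencies of each rank over
draws, and SUCRA is the average of the cumulative rank probabilities over
the first K-1 ranks — 1 for a treatment certainly best, 0 certainly worst,
mean exactly 0.5 across treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nma import PosteriorSamples

__all__ = ["SucraResult", "rank_probabilities", "sucra", "rank_treatments"]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class SucraResult:
    treatments: tuple[str, ...]
    rank_probability: np.ndarray  # (K, K): row treatment, column rank (0 = best)
    cumulative_rank: np.ndarray  # running sums over ranks
    sucra: np.ndarray  # (K,) in [0, 1]

    @property
    def sucra_percent(self) -> np.ndarray:
        """SUCRA in percent, rounded to 2 decimals for reporting."""
        return np.round(100.0 * self.sucra, 2)

    def for_treatment(self, treatment: str) -> float:
        return float(self.sucra[self.treatments.index(treatment)])

    def to_dataframe(self) -> pd.DataFrame:
        k = len(self.treatments)
        df = pd.DataFrame(
            self.rank_probability,
            index=self.treatments,
            columns=[f"rank_{r + 1}" for r in range(k)],
        )
        df["sucra"] = self.sucra
        return df

    def rankogram_long(self) -> pd.DataFrame:
        """Long-format rank probabilities, ready for plotting layers."""
        k = len(self.treatments)
        rows = [
            {
                "treatment": t,
                "rank": r + 1,
                "probability": self.rank_probability[i, r],
                "cumulative": self.cumulative_rank[i, r],
            }
            for i, t in enumerate(self.treatments)
            for r in range(k)
        ]
        return pd.DataFrame(rows)


def rank_probabilities(samples: PosteriorSamples, direction: str) -> np.ndarray:
    """(K, K) matrix of Pr(treatment i has rank j), rank 1 = best.

    ``direction`` is the outcome's ``better_direction``.  Exact ties within
    a draw (possible only at the reference's zero effect) break by fixed
    treatment order via a stable sort.
    """
    if direction not in ("lower", "higher"):
        raise ValueError(f"unknown direction {direction!r}")
    d = samples.d_matrix()  # (n_draws, K)
    keys = d if direction == "lower" else -d
    order = np.argsort(keys, axis=1, kind="stable")  # best ... worst
    n, k = d.shape
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(k)[None, :]
    probs = np.zeros((k, k))
    for t in range(k):
        probs[t] = np.bincount(ranks[:, t], minlength=k) / n
    return probs


def sucra(rank_probability: np.ndarray) -> np.ndarray:
    """SUCRA_k = mean of cumulative rank probabilities over ranks 1..K-1."""
    probs = np.asarray(rank_probability, float)
    k = probs.shape[0]
    if probs.shape != (k, k) or k < 2:
        raise ValueError("rank probability matrix must be square, K >= 2")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rank probability rows must sum to 1")
    cum = np.cumsum(probs, axis=1)
    return cum[:, : k - 1].mean(axis=1)


def rank_treatments(samples: PosteriorSamples, direction: str) -> SucraResult:
    """Full ranking summary from posterior samples."""
    probs = rank_probabilities(samples, direction)
    cum = np.cumsum(probs, axis=1)
    return SucraResult(
        treatments=samples.treatments,
        rank_probability=probs,
        cumulative_rank=cum,
        sucra=sucra(probs),
    )
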