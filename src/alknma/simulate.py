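"""Synthetic two-arm evidence networks with known ground truth.

Data are generated from exactly the model the NMA engine fits: trial
effects drawn Normal(d_alt - d_ref, tau^2), observed either as a contrast
with known SE or as binomial arm counts under a logit link with jittered
trial baselines.  Every stage of the pipeline is therefore testable for
parameter recovery without any external data.

Draw order per trial (one seeded generator per dataset, in fixed trial
order): contrast networks draw (se, delta, y); binary networks draw
(arm sizes if ranged, baseline jitter, delta, experimental events,
control events).  Identical configs reproduce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    BinaryArmObservation,
    ContrastObservation,
    EvidenceNetwork,
    OutcomeSpec,
    build_network,
)

__all__ = ["SyntheticConfig", "PAPER_LIKE_EDGES", "generate_contrast_network", "generate_binary_network"]

#: Edge multiset of the bundled 12-trial ALK network: (ref, alt, n_trials).
PAPER_LIKE_EDGES = (
    ("chemotherapy", "crizotinib", 3),
    ("chemotherapy", "alectinib", 1),
    ("chemotherapy", "ceritinib", 2),
    ("crizotinib", "alectinib", 3),
    ("crizotinib", "brigatinib", 1),
    ("crizotinib", "lorlatinib", 1),
    ("crizotinib", "ensartinib", 1),
)

PAPER_LIKE_TREATMENTS = (
    "chemotherapy",
    "crizotinib",
    "alectinib",
    "ceritinib",
    "brigatinib",
    "lorlatinib",
    "ensartinib",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and shape of a synthetic network.

    ``true_basic_effects`` are the log relative effects d_k of each
    treatment versus the first (which is the reference, d_1 = 0); length
    must equal the number of treatments.  ``contrast_se`` and ``arm_size``
    may be scalars or (low, high) ranges sampled per trial.
    """

    n_treatments: int = 3
    topology: str = "star"  # 'star' | 'loop' | 'paper_like'
    true_basic_effects: tuple[float, ...] = (0.0, -0.5, -1.0)
    heterogeneity_sd: float = 0.1
    trials_per_edge: int = 2
    arm_size: int | tuple[int, int] = 150
    baseline_event_prob: float = 0.4
    contrast_se: float | tuple[float, float] = (0.1, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("star", "loop", "paper_like"):
            raise ValueError(f"unknown topology {self.topology!r}")
        k = 7 if self.topology == "paper_like" else self.n_treatments
        if k < 2:
            raise ValueError("need at least 2 treatments")
        if len(self.true_basic_effects) != k:
            raise ValueError(
                f"true_basic_effects must have length {k} for this topology"
            )
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be non-negative")
        if not 0.0 < self.baseline_event_prob < 1.0:
            raise ValueError("baseline_event_prob must lie in (0, 1)")

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        if self.topology == "paper_like":
            return PAPER_LIKE_TREATMENTS
        return tuple(f"t{i + 1}" for i in range(self.n_treatments))

    def edge_list(self) -> list[tuple[str, str]]:
        """(ref, alt) per trial, in generation order."""
        ids = self.treatment_ids
        if self.topology == "paper_like":
            return [
                (ref, alt)
                for ref, alt, count in PAPER_LIKE_EDGES
                for _ in range(count)
            ]
        if self.topology == "star":
            pairs = [(ids[0], t) for t in ids[1:]]
        else:  # loop
            pairs = [(ids[i], ids[(i + 1) % len(ids)]) for i in range(len(ids))]
            pairs = [(min(a, b, key=list(ids).index), max(a, b, key=list(ids).index)) for a, b in pairs]
        return [pair for pair in pairs for _ in range(self.trials_per_edge)]

    def effect(self, treatment: str) -> float:
        return self.true_basic_effects[self.treatment_ids.index(treatment)]

    def true_contrast(self, alt: str, ref: str) -> float:
        return self.effect(alt) - self.effect(ref)


def _draw_range(rng: np.random.Generator, value, integer: bool = False):
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1)) if integer else float(rng.uniform(lo, hi))
    return value


def generate_contrast_network(config: SyntheticConfig) -> EvidenceNetwork:
    """Synthetic contrast-level (log hazard ratio) network."""
    rng = np.random.default_rng(config.seed)
    outcome = OutcomeSpec("sim", "contrast_loghr", "lower")
    obs = []
    for i, (ref, alt) in enumerate(config.edge_list()):
        se = _draw_range(rng, config.contrast_se)
        delta = rng.normal(config.true_contrast(alt, ref), config.heterogeneity_sd)
        y = rng.normal(delta, se)
        obs.append(
            ContrastObservation(
                trial_id=f"S{i + 1:02d}",
                treat_ref=ref,
                treat_alt=alt,
                log_effect=float(y),
                se=float(se),
                outcome_id="sim",
            )
        )
    return build_network(obs, outcome)


def generate_binary_network(config: SyntheticConfig) -> EvidenceNetwork:
    """Synthetic arm-level binomial network under the logit model.

    Trial baselines mu_i get Normal(0, 0.1) jitter around
    logit(baseline_event_prob); the experimental arm is listed first in
    each trial, matching the loader convention for arm order.
    """
    rng = np.random.default_rng(config.seed)
    outcome = OutcomeSpec("sim", "arm_binary", "lower")
    base_logit = float(np.log(config.baseline_event_prob / (1 - config.baseline_event_prob)))
    obs = []
    for i, (ref, alt) in enumerate(config.edge_list()):
        trial = f"S{i + 1:02d}"
        n_alt = _draw_range(rng, config.arm_size, integer=True)
        n_ref = _draw_range(rng, config.arm_size, integer=True)
        mu = base_logit + rng.normal(0.0, 0.1)
        delta = rng.normal(config.true_contrast(alt, ref), config.heterogeneity_sd)
        p_ref = 1.0 / (1.0 + np.exp(-mu))
        p_alt = 1.0 / (1.0 + np.exp(-(mu + delta)))
        r_alt = int(rng.binomial(n_alt, p_alt))
        r_ref = int(rng.binomial(n_ref, p_ref))
        obs.append(BinaryArmObservation(trial, alt, n_alt, r_alt, "sim"))
        obs.append(BinaryArmObservation(trial, ref, n_ref, r_ref, "sim"))
    return build_network(obs, outcome)
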