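"""Evidence-network data model for contrast- and arm-level trial summaries.

A network meta-analysis combines randomized comparisons between several
treatments into a single connected evidence graph.  Trials enter either as
*contrast-level* records (a log hazard ratio with its standard error,
recovered from a published HR and 95% CI) or as *arm-level* binary records
(event counts reconstructed from published percentages and arm sizes).

All downstream stages (pairwise pooling, the Bayesian NMA engine, ranking,
bias diagnostics) consume the :class:`EvidenceNetwork` defined here.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "Z_95",
    "Treatment",
    "OutcomeSpec",
    "ContrastObservation",
    "BinaryArmObservation",
    "EvidenceNetwork",
    "derive_log_hr",
    "reconstruct_events",
    "build_network",
    "read_contrast_csv",
    "read_arm_csv",
    "write_network_csv",
    "read_network_csv",
]

#: Two-sided 95% normal quantile used to recover SEs from CI widths.
#: The unrounded value keeps derived SEs reproducible to 4 decimals.
Z_95 = 1.959964


@dataclass(frozen=True)
class Treatment:
    """A node of the evidence network."""

    id: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("treatment id must be non-empty")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)


@dataclass(frozen=True)
class OutcomeSpec:
    """What an outcome measures and which direction is clinically better.

    ``better_direction`` is fixed before any ranking: 'lower' for hazards
    and adverse-event odds, 'higher' for response odds.
    """

    outcome_id: str
    data_kind: str  # 'contrast_loghr' | 'arm_binary'
    better_direction: str  # 'lower' | 'higher'

    def __post_init__(self) -> None:
        if self.data_kind not in ("contrast_loghr", "arm_binary"):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")
        if self.better_direction not in ("lower", "higher"):
            raise ValueError(f"unknown better_direction {self.better_direction!r}")


@dataclass(frozen=True)
class ContrastObservation:
    """One trial's log relative effect (y_i) with its standard error (s_i).

    ``treat_ref`` is the denominator of the published ratio (the control
    arm), ``treat_alt`` the numerator (the experimental arm).
    """

    trial_id: str
    treat_ref: str
    treat_alt: str
    log_effect: float
    se: float
    outcome_id: str

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.trial_id}: se must be positive, got {self.se}")
        if self.treat_ref == self.treat_alt:
            raise ValueError(f"{self.trial_id}: contrast needs two distinct treatments")


@dataclass(frozen=True)
class BinaryArmObservation:
    """One arm's event count r_ik out of n_ik randomized patients."""

    trial_id: str
    treatment: str
    n: int
    events: int
    outcome_id: str

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.trial_id}/{self.treatment}: arm size must be positive")
        if not 0 <= self.events <= self.n:
            raise ValueError(
                f"{self.trial_id}/{self.treatment}: events {self.events} outside [0, {self.n}]"
            )


Observation = Union[ContrastObservation, BinaryArmObservation]


class DisconnectedNetworkError(ValueError):
    """Raised when the evidence graph does not connect all treatments."""

    def __init__(self, components: Sequence[frozenset]) -> None:
        self.components = list(components)
        smallest = sorted(min(self.components, key=len))
        super().__init__(
            f"evidence network is disconnected: component {smallest} is isolated "
            f"({len(self.components)} components in total)"
        )


@dataclass(frozen=True)
class EvidenceNetwork:
    """A connected evidence graph for one outcome.

    ``edges`` maps each unordered treatment pair (a frozenset of two ids)
    to the number of trials comparing that pair directly.
    """

    treatments: tuple[Treatment, ...]
    outcome: OutcomeSpec
    observations: tuple[Observation, ...]
    edges: dict = field(default_factory=dict)

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.treatments)

    @property
    def trial_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.trial_id, None)
        return tuple(seen)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatment_ids)
        for pair, count in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, trials=count)
        return g

    def trial_contrasts(self) -> list[tuple[str, str, str]]:
        """Per-trial (trial_id, ref, alt) contrast structure.

        For arm-level data the control arm is the one listed second in the
        source tables; loaders preserve that order, so the first arm of a
        trial is the experimental arm.
        """
        if self.outcome.data_kind == "contrast_loghr":
            return [(o.trial_id, o.treat_ref, o.treat_alt) for o in self.observations]
        out: list[tuple[str, str, str]] = []
        by_trial: dict[str, list[BinaryArmObservation]] = {}
        for obs in self.observations:
            by_trial.setdefault(obs.trial_id, []).append(obs)
        for trial, arms in by_trial.items():
            if len(arms) != 2:
                raise ValueError(f"trial {trial} has {len(arms)} arms; exactly 2 supported")
            alt, ref = arms
            out.append((trial, ref.treatment, alt.treatment))
        return out

    def arms_by_trial(self) -> dict[str, tuple[BinaryArmObservation, BinaryArmObservation]]:
        """(experimental, control) arm pair per trial, for binary outcomes."""
        if self.outcome.data_kind != "arm_binary":
            raise ValueError("arm pairs only defined for arm-level binary outcomes")
        by_trial: dict[str, list[BinaryArmObservation]] = {}
        for obs in self.observations:
            by_trial.setdefault(obs.trial_id, []).append(obs)
        return {t: (arms[0], arms[1]) for t, arms in by_trial.items()}

    def drop_trial(self, trial_id: str) -> "EvidenceNetwork":
        """Network without one trial (treatments left with no evidence are dropped)."""
        remaining = [o for o in self.observations if o.trial_id != trial_id]
        if not remaining:
            raise ValueError(f"dropping {trial_id!r} leaves no observations")
        return build_network(remaining, self.outcome)


def derive_log_hr(hr: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (log HR, SE) from a published hazard ratio and 95% CI.

    The SE is the CI width on the log scale divided by twice the 95%
    normal quantile: ``(ln ci_high - ln ci_low) / (2 * 1.959964)``.
    """
    if hr <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ValueError("hazard ratio and CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError(f"ci_low {ci_low} exceeds ci_high {ci_high}")
    if not ci_low <= hr <= ci_high:
        raise ValueError(f"hr {hr} outside its own CI [{ci_low}, {ci_high}]")
    if ci_low == ci_high:
        raise ValueError("zero-width CI: standard error undefined")
    log_effect = math.log(hr)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return log_effect, se


def reconstruct_events(percent: float, n: int) -> int:
    """Event count from a published percentage: round(percent*n/100), ties to even."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent {percent} outside [0, 100]")
    if n <= 0:
        raise ValueError("arm size must be positive")
    events = round(percent * n / 100.0)  # Python rounds half to even
    return min(max(events, 0), n)


def build_network(
    observations: Iterable[Observation],
    outcome: OutcomeSpec,
    treatments: Iterable[Treatment] | None = None,
) -> EvidenceNetwork:
    """Assemble and validate an :class:`EvidenceNetwork`.

    Deduplicates treatments, counts trials per edge, and certifies
    connectivity; a disconnected graph raises
    :class:`DisconnectedNetworkError` naming the isolated component.
    """
    obs = tuple(observations)
    if not obs:
        raise ValueError("no observations")
    known = {t.id: t for t in treatments} if treatments else {}

    ids: dict[str, None] = {}
    for o in obs:
        if o.outcome_id != outcome.outcome_id:
            raise ValueError(
                f"observation {o.trial_id} is for outcome {o.outcome_id!r}, "
                f"not {outcome.outcome_id!r}"
            )
        labels = (
            (o.treat_ref, o.treat_alt)
            if isinstance(o, ContrastObservation)
            else (o.treatment,)
        )
        for lab in labels:
            if known and lab not in known:
                raise KeyError(f"unknown treatment label {lab!r}")
            ids.setdefault(lab, None)
    if len(ids) < 2:
        raise ValueError("a network needs at least 2 treatments")

    treatment_tuple = tuple(known[i] if known else Treatment(i) for i in ids)

    # one edge per trial; arm-level trials contribute their (exp, ctrl) pair
    seen_keys: set[tuple[str, str]] = set()
    per_trial_pairs: dict[str, set[str]] = {}
    for o in obs:
        key = (o.trial_id, getattr(o, "treatment", "")) if isinstance(
            o, BinaryArmObservation
        ) else (o.trial_id, "")
        if isinstance(o, ContrastObservation):
            if key in seen_keys:
                raise ValueError(f"duplicate contrast for trial {o.trial_id}")
        elif key in seen_keys:
            raise ValueError(f"duplicate arm {o.treatment} in trial {o.trial_id}")
        seen_keys.add(key)
        per_trial_pairs.setdefault(o.trial_id, set()).update(
            (o.treat_ref, o.treat_alt) if isinstance(o, ContrastObservation) else (o.treatment,)
        )

    edge_counts: Counter = Counter()
    for trial, members in per_trial_pairs.items():
        if len(members) != 2:
            raise ValueError(
                f"trial {trial} involves {len(members)} treatments; only two-arm trials supported"
            )
        edge_counts[frozenset(members)] += 1

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(tuple(sorted(pair)) for pair in edge_counts)
    if not nx.is_connected(g):
        comps = [frozenset(c) for c in nx.connected_components(g)]
        raise DisconnectedNetworkError(comps)

    return EvidenceNetwork(
        treatments=treatment_tuple,
        outcome=outcome,
        observations=obs,
        edges=dict(edge_counts),
    )


# ---------------------------------------------------------------------------
# Delimited text I/O.  Two dialects:
#   contrasts: trial,treat_ref,treat_alt,hr,ci_low,ci_high,outcome
#   arms:      trial,treatment,n,percent,outcome
# ---------------------------------------------------------------------------

CONTRAST_COLUMNS = ["trial", "treat_ref", "treat_alt", "hr", "ci_low", "ci_high", "outcome"]
ARM_COLUMNS = ["trial", "treatment", "n", "percent", "outcome"]


def read_contrast_csv(path, outcome_id: str | None = None) -> list[ContrastObservation]:
    """Read contrast-level records, deriving log effects and SEs from the CIs."""
    df = pd.read_csv(path)
    missing = set(CONTRAST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contrast CSV missing columns: {sorted(missing)}")
    if outcome_id is not None:
        df = df[df["outcome"] == outcome_id]
    out = []
    for row in df.itertuples(index=False):
        log_effect, se = derive_log_hr(row.hr, row.ci_low, row.ci_high)
        out.append(
            ContrastObservation(
                trial_id=str(row.trial),
                treat_ref=str(row.treat_ref),
                treat_alt=str(row.treat_alt),
                log_effect=log_effect,
                se=se,
                outcome_id=str(row.outcome),
            )
        )
    return out


def read_arm_csv(path, outcome_id: str | None = None) -> list[BinaryArmObservation]:
    """Read arm-level records, reconstructing event counts from percentages."""
    df = pd.read_csv(path)
    missing = set(ARM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"arm CSV missing columns: {sorted(missing)}")
    if outcome_id is not None:
        df = df[df["outcome"] == outcome_id]
    return [
        BinaryArmObservation(
            trial_id=str(row.trial),
            treatment=str(row.treatment),
            n=int(row.n),
            events=reconstruct_events(float(row.percent), int(row.n)),
            outcome_id=str(row.outcome),
        )
        for row in df.itertuples(index=False)
    ]


def write_network_csv(network: EvidenceNetwork, path) -> None:
    """Write a network back to its delimited dialect (round-trips exactly)."""
    path = Path(path)
    if network.outcome.data_kind == "contrast_loghr":
        rows = [
            {
                "trial": o.trial_id,
                "treat_ref": o.treat_ref,
                "treat_alt": o.treat_alt,
                "hr": math.exp(o.log_effect),
                "ci_low": math.exp(o.log_effect - Z_95 * o.se),
                "ci_high": math.exp(o.log_effect + Z_95 * o.se),
                "outcome": o.outcome_id,
            }
            for o in network.observations
        ]
        pd.DataFrame(rows, columns=CONTRAST_COLUMNS).to_csv(path, index=False)
    else:
        rows = [
            {
                "trial": o.trial_id,
                "treatment": o.treatment,
                "n": o.n,
                "percent": 100.0 * o.events / o.n,
                "outcome": o.outcome_id,
            }
            for o in network.observations
        ]
        pd.DataFrame(rows, columns=ARM_COLUMNS).to_csv(path, index=False)


def read_network_csv(path, outcome: OutcomeSpec) -> EvidenceNetwork:
    """Read a network from either CSV dialect, selecting rows for ``outcome``."""
    if outcome.data_kind == "contrast_loghr":
        obs = read_contrast_csv(path, outcome.outcome_id)
    else:
        obs = read_arm_csv(path, outcome.outcome_id)
    return build_network(obs, outcome)
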