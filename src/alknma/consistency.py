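"""Local and global inconsistency assessment.

Node-splitting refits the network with a separate *direct* parameter for
one edge while the remaining trials inform the *indirect* contrast through
the basic parameters; a two-sided Bayesian p-value on the direct-indirect
difference flags disagreement.  The unrelated-mean-effects (UME) model —
every observed comparison with its own free parameter — serves as the
global benchmark via DIC comparison against the consistency model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mcmc import RawDraws
from .network import EvidenceNetwork
from .nma import (
    NmaModelSpec,
    PosteriorSamples,
    _sample_design,
    bayesian_p,
    consistency_design,
    fit_nma,
    gelman_rubin,
)

__all__ = ["NodeSplitResult", "splittable_edges", "node_split", "node_split_all", "fit_ume"]

DIRECT_PARAM = "direct"


@dataclass(frozen=True)
class NodeSplitResult:
    edge: tuple[str, str]  # (ref, alt); estimates are alt vs ref, log scale
    direct_estimate: tuple[float, tuple[float, float]]
    indirect_estimate: tuple[float, tuple[float, float]]
    network_estimate: tuple[float, tuple[float, float]]
    bayes_p: float

    @property
    def consistent(self) -> bool:
        return self.bayes_p >= 0.05


def splittable_edges(network: EvidenceNetwork) -> list[tuple[str, str]]:
    """Edges with both direct evidence and an independent indirect path.

    These are exactly the edges lying on a cycle of the comparison graph,
    i.e. the non-bridge edges.  Pairs are returned oriented (ref, alt) as
    in the first trial on the edge.
    """
    g = network.graph()
    bridges = {frozenset(e) for e in nx.bridges(g)}
    orient: dict[frozenset, tuple[str, str]] = {}
    for _, ref, alt in network.trial_contrasts():
        orient.setdefault(frozenset((ref, alt)), (ref, alt))
    return [orient[key] for key in orient if key not in bridges]


def _split_design(
    network: EvidenceNetwork, reference: str, edge: tuple[str, str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Consistency design plus one direct column for the split edge."""
    X, params, trials = consistency_design(network, reference)
    key = frozenset(edge)
    n = X.shape[0]
    col = np.zeros((n, 1))
    for i, (_, ref, alt) in enumerate(network.trial_contrasts()):
        if frozenset((ref, alt)) == key:
            X[i, :] = 0.0
            col[i, 0] = 1.0 if (ref, alt) == edge else -1.0
    return np.hstack([X, col]), params + [DIRECT_PARAM], trials


def _summ(draws: np.ndarray) -> tuple[float, tuple[float, float]]:
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
    return float(med), (float(lo), float(hi))


def node_split(
    network: EvidenceNetwork,
    edge: tuple[str, str],
    spec: NmaModelSpec = NmaModelSpec(),
    network_fit: PosteriorSamples | None = None,
) -> NodeSplitResult:
    """Split one edge into direct and indirect evidence and compare them."""
    splittable = {frozenset(e) for e in splittable_edges(network)}
    if frozenset(edge) not in splittable:
        raise ValueError(f"edge {edge} is not splittable (no independent loop)")
    reference = spec.reference or network.treatment_ids[0]
    X, params, trials = _split_design(network, reference, edge)
    raw: RawDraws = _sample_design(network, spec, X, trials)
    samples = PosteriorSamples(
        param_names=tuple(params),
        treatments=network.treatment_ids,
        reference=reference,
        trial_ids=tuple(trials),
        raw=raw,
        spec=spec,
        data_kind=network.outcome.data_kind,
        parameterization="nodesplit",
    )
    samples.convergence = gelman_rubin(samples)

    direct = raw.beta[:, :, -1].reshape(-1)

    def basic(t: str) -> np.ndarray:
        if t == reference:
            return np.zeros(direct.shape)
        return raw.beta[:, :, params.index(t)].reshape(-1)

    ref_t, alt_t = edge
    indirect = basic(alt_t) - basic(ref_t)

    if network_fit is None:
        network_fit = fit_nma(network, spec, check_convergence=False)
    net = network_fit.contrast_draws(alt_t, ref_t)

    return NodeSplitResult(
        edge=edge,
        direct_estimate=_summ(direct),
        indirect_estimate=_summ(indirect),
        network_estimate=_summ(net),
        bayes_p=bayesian_p(direct - indirect),
    )


def node_split_all(
    network: EvidenceNetwork,
    spec: NmaModelSpec = NmaModelSpec(),
    network_fit: PosteriorSamples | None = None,
) -> pd.DataFrame:
    """Node-split summary table over all splittable edges."""
    if network_fit is None:
        network_fit = fit_nma(network, spec, check_convergence=False)
    rows = []
    for i, edge in enumerate(splittable_edges(network)):
        res = node_split(
            network, edge, spec.with_(seed=spec.seed + 101 * (i + 1)), network_fit
        )
        rows.append(
            {
                "edge": f"{edge[1]}.vs.{edge[0]}",
                "direct": res.direct_estimate[0],
                "direct_low": res.direct_estimate[1][0],
                "direct_high": res.direct_estimate[1][1],
                "indirect": res.indirect_estimate[0],
                "indirect_low": res.indirect_estimate[1][0],
                "indirect_high": res.indirect_estimate[1][1],
                "network": res.network_estimate[0],
                "bayes_p": res.bayes_p,
            }
        )
    return pd.DataFrame(rows)


def fit_ume(network: EvidenceNetwork, spec: NmaModelSpec = NmaModelSpec()) -> PosteriorSamples:
    """Fit the unrelated-mean-effects (inconsistency) model."""
    return fit_nma(network, spec.with_(consistency="ume_inconsistent"))
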