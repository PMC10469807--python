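"""Sensitivity analyses: leave-one-out refits and FE-vs-RE agreement.

Leave-one-out drops each trial in turn and refits the network, reporting
the pairwise contrasts of every remaining comparison; exclusions that
disconnect the network (or drop a treatment entirely) are reported rather
than raised.  The Bland-Altman comparison quantifies agreement between
fixed- and random-effects league tables on the log scale.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DisconnectedNetworkError, EvidenceNetwork
from .nma import LeagueTable, NmaModelSpec, fit_nma, league_table

__all__ = ["leave_one_out", "BlandAltmanResult", "bland_altman_fe_re"]


def _trial_seed(base: int, trial_id: str) -> int:
    """Reproducible per-trial seed: primary seed plus a trial-id offset."""
    return (base + zlib.crc32(trial_id.encode()) % 100_000) % (2**31 - 1)


def leave_one_out(
    network: EvidenceNetwork,
    spec: NmaModelSpec = NmaModelSpec(),
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One NMA refit per excluded trial.

    Returns a long-format table (excluded_trial, column treatment, row
    treatment, median, low, high, note).  ``pairs`` restricts the reported
    contrasts; by default every ordered pair of surviving treatments is
    reported.  Effects are ratios of the column treatment versus the row
    treatment, as in the league table.
    """
    rows = []
    for trial in network.trial_ids:
        note = ""
        try:
            sub = network.drop_trial(trial)
        except DisconnectedNetworkError:
            rows.append(
                {"excluded_trial": trial, "treat_col": "", "treat_row": "",
                 "median": math.nan, "low": math.nan, "high": math.nan,
                 "note": "disconnects network"}
            )
            continue
        dropped = set(network.treatment_ids) - set(sub.treatment_ids)
        if dropped:
            note = f"treatment dropped: {', '.join(sorted(dropped))}"
        sub_spec = spec.with_(seed=_trial_seed(spec.seed, trial))
        if spec.reference is not None and spec.reference not in sub.treatment_ids:
            sub_spec = sub_spec.with_(reference=sub.treatment_ids[0])
        fit = fit_nma(sub, sub_spec, check_convergence=False)
        table = league_table(fit)
        wanted = pairs or [
            (a, b)
            for a in sub.treatment_ids
            for b in sub.treatment_ids
            if a != b
        ]
        for col, row in wanted:
            if col not in sub.treatment_ids or row not in sub.treatment_ids:
                rows.append(
                    {"excluded_trial": trial, "treat_col": col, "treat_row": row,
                     "median": math.nan, "low": math.nan, "high": math.nan,
                     "note": note or "treatment absent"}
                )
                continue
            cell = table.entry(col, row)
            rows.append(
                {"excluded_trial": trial, "treat_col": col, "treat_row": row,
                 "median": cell["median"], "low": cell["ci95"][0],
                 "high": cell["ci95"][1], "note": note}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    limits: tuple[float, float]  # mean +- 1.96 sd of the differences
    table: pd.DataFrame  # per-comparison log-scale differences

    @property
    def agreement(self) -> bool:
        """Zero mean-difference lies within the limits of agreement."""
        return self.limits[0] <= 0.0 <= self.limits[1]


def bland_altman_fe_re(fe: LeagueTable, re: LeagueTable) -> BlandAltmanResult:
    """Bland-Altman agreement of FE and RE league tables (log scale).

    One paired difference per unordered treatment pair (upper triangle).
    """
    if fe.treatments != re.treatments:
        raise ValueError("league tables cover different comparison sets")
    k = len(fe.treatments)
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            lf = math.log(fe.median[i, j])
            lr = math.log(re.median[i, j])
            recs.append(
                {
                    "comparison": f"{fe.treatments[j]}.vs.{fe.treatments[i]}",
                    "fe_log": lf,
                    "re_log": lr,
                    "mean": 0.5 * (lf + lr),
                    "diff": lf - lr,
                }
            )
    table = pd.DataFrame(recs)
    diffs = table["diff"].to_numpy()
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return BlandAltmanResult(
        mean_diff=mean, limits=(mean - 1.96 * sd, mean + 1.96 * sd), table=table
    )
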