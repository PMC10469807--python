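"""End-to-end report assembly: every pipeline stage per outcome, as CSV.

``run_full_analysis`` orchestrates the stages for each requested outcome —
pairwise forest tables, fixed- and random-effects league tables, SUCRA,
convergence diagnostics, DIC consistency-vs-UME comparison, node-splitting,
funnel/Egger/Begg/trim-and-fill diagnostics, Bland-Altman agreement and
(optionally) leave-one-out refits — and writes plot-ready CSVs plus a run
log.  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import begg_test, comparison_adjusted_funnel, egger_test, network_effects, trim_and_fill
from .consistency import fit_ume, node_split_all
from .fixtures import OUTCOMES, load_fixture
from .network import OutcomeSpec, read_network_csv
from .nma import NmaModelSpec, compute_dic, fit_nma, league_table
from .pairwise import direct_comparisons, comparison_effects
from .ranking import rank_treatments
from .sensitivity import bland_altman_fe_re, leave_one_out

logger = logging.getLogger("alknma")

__all__ = ["ReportConfig", "parse_config", "run_full_analysis"]

_KNOWN_KEYS = {
    "outcomes",
    "contrasts_csv",
    "arms_csv",
    "reference",
    "chains",
    "burn_in",
    "kept_iterations",
    "thin",
    "seed",
    "loo",
    "tau_upper",
}


@dataclass(frozen=True)
class ReportConfig:
    outcomes: tuple[str, ...] = tuple(OUTCOMES)
    contrasts_csv: str = "fixture"
    arms_csv: str = "fixture"
    reference: str | None = None
    chains: int = 4
    burn_in: int = 10_000
    kept_iterations: int = 50_000
    thin: int = 2
    seed: int = 20230619
    loo: bool = False
    tau_upper: float | None = None

    def model_spec(self, effect_model: str = "random", seed_offset: int = 0) -> NmaModelSpec:
        return NmaModelSpec(
            effect_model=effect_model,
            reference=self.reference,
            chains=self.chains,
            burn_in=self.burn_in,
            kept_iterations=self.kept_iterations,
            thin=self.thin,
            seed=self.seed + seed_offset,
            tau_upper=self.tau_upper,
        )


def parse_config(path) -> ReportConfig:
    """Plain-text ``key = value`` config; '#' starts a comment."""
    path = Path(path)
    values: dict[str, str] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{line_no}: expected 'key = value'")
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    unknown = sorted(set(values) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    kwargs: dict = {}
    if "outcomes" in values:
        kwargs["outcomes"] = tuple(x.strip() for x in values["outcomes"].split(",") if x.strip())
    for key in ("contrasts_csv", "arms_csv", "reference"):
        if key in values:
            kwargs[key] = values[key]
    for key in ("chains", "burn_in", "kept_iterations", "thin", "seed"):
        if key in values:
            kwargs[key] = int(values[key])
    if "tau_upper" in values:
        kwargs["tau_upper"] = float(values["tau_upper"])
    if "loo" in values:
        kwargs["loo"] = values["loo"].lower() in ("1", "true", "yes")
    return ReportConfig(**kwargs)


def _load_network(config: ReportConfig, outcome_id: str):
    if outcome_id in OUTCOMES:
        spec = OUTCOMES[outcome_id]
    else:
        spec = OutcomeSpec(outcome_id, "contrast_loghr", "lower")
    source = (
        config.contrasts_csv if spec.data_kind == "contrast_loghr" else config.arms_csv
    )
    if source == "fixture":
        if outcome_id not in OUTCOMES:
            raise KeyError(f"outcome {outcome_id!r} is not part of the bundled dataset")
        return load_fixture(outcome_id)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"data file not found: {path}")
    return read_network_csv(path, spec)


def _forest_table(network) -> pd.DataFrame:
    rows = []
    for pair, studies in comparison_effects(network).items():
        fe = direct_comparisons(network, "fixed")[pair]
        re = direct_comparisons(network, "random")[pair]
        w_sum = sum(1.0 / s**2 for _, _, s in studies)
        for trial, y, s in studies:
            rows.append(
                {"comparison": f"{pair[1]}.vs.{pair[0]}", "study": trial,
                 "log_effect": y, "se": s,
                 "ratio": math.exp(y),
                 "weight_pct": 100.0 * (1.0 / s**2) / w_sum,
                 "row_kind": "study"}
            )
        for res in (fe, re):
            rows.append(
                {"comparison": f"{pair[1]}.vs.{pair[0]}", "study": f"pooled_{res.model}",
                 "log_effect": res.pooled_log_effect, "se": res.pooled_se,
                 "ratio": res.pooled_ratio,
                 "weight_pct": 100.0, "row_kind": f"pooled_{res.model}",
                 "Q": res.Q, "df": res.df, "i_squared": res.i_squared,
                 "tau_squared": res.tau_squared}
            )
    return pd.DataFrame(rows)


def _league_long(table) -> pd.DataFrame:
    rows = []
    k = len(table.treatments)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            rows.append(
                {"column": table.treatments[j], "row": table.treatments[i],
                 "median": table.median[i, j], "low": table.low[i, j],
                 "high": table.high[i, j], "bayes_p": table.bayes_p[i, j],
                 "significant": table.bayes_p[i, j] < 0.05}
            )
    return pd.DataFrame(rows)


def run_full_analysis(config: ReportConfig | str | Path, out_dir) -> dict:
    """Run the full pipeline; returns a summary dict with a 'flagged' field.

    ``flagged`` is True when any MCMC fit failed the PSRF < 1.05 check;
    reports are still emitted in that case.
    """
    if not isinstance(config, ReportConfig):
        config = parse_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    flagged: list[str] = []
    log_lines = [
        f"alknma {__version__}",
        f"seed = {config.seed}",
        f"sampler = {config.chains} chains, burn-in {config.burn_in}, "
        f"kept {config.kept_iterations}, thin {config.thin}",
        f"outcomes = {', '.join(config.outcomes)}",
    ]

    for idx, outcome_id in enumerate(config.outcomes):
        t0 = time.time()
        network = _load_network(config, outcome_id)
        odir = out / outcome_id
        odir.mkdir(exist_ok=True)
        logger.info(
            "%s: %d treatments, %d trials, %d edges",
            outcome_id, len(network.treatments), network.n_trials, len(network.edges),
        )

        _forest_table(network).to_csv(odir / "pairwise_forest.csv", index=False)

        spec_re = config.model_spec("random", seed_offset=idx)
        spec_fe = config.model_spec("fixed", seed_offset=idx)
        fit_re = fit_nma(network, spec_re)
        fit_fe = fit_nma(network, spec_fe)
        if fit_re.convergence is not None and not fit_re.convergence.passed:
            flagged.append(outcome_id)

        lt_re = league_table(fit_re)
        lt_fe = league_table(fit_fe)
        lt_re.to_dataframe().to_csv(odir / "league_random.csv")
        _league_long(lt_re).to_csv(odir / "league_random_long.csv", index=False)
        lt_fe.to_dataframe().to_csv(odir / "league_fixed.csv")

        ranking = rank_treatments(fit_re, network.outcome.better_direction)
        ranking.to_dataframe().to_csv(odir / "sucra.csv")
        ranking.rankogram_long().to_csv(odir / "rankogram.csv", index=False)

        conv = fit_re.convergence
        pd.DataFrame(
            {"parameter": list(conv.psrf), "psrf": list(conv.psrf.values()),
             "ess": [conv.ess[k] for k in conv.psrf]}
        ).to_csv(odir / "convergence.csv", index=False)

        dbar_c, pd_c, dic_c = compute_dic(fit_re, network)
        ume = fit_ume(network, spec_re.with_(seed=spec_re.seed + 7))
        dbar_u, pd_u, dic_u = compute_dic(ume, network)
        pd.DataFrame(
            [{"model": "consistency", "Dbar": dbar_c, "pD": pd_c, "DIC": dic_c},
             {"model": "ume_inconsistency", "Dbar": dbar_u, "pD": pd_u, "DIC": dic_u}]
        ).to_csv(odir / "dic.csv", index=False)

        ns = node_split_all(network, spec_re, network_fit=fit_re)
        ns.to_csv(odir / "node_split.csv", index=False)

        points = comparison_adjusted_funnel(network)
        pd.DataFrame(
            [{"study": p.study, "centered_effect": p.centered_effect, "se": p.se,
              "comparison": f"{p.comparison[1]}.vs.{p.comparison[0]}",
              "imputed": p.imputed} for p in points]
        ).to_csv(odir / "funnel_points.csv", index=False)

        effects = [(y, s) for _, y, s in network_effects(network)]
        egger = egger_test(effects)
        begg = begg_test(effects)
        bias_rows = [
            {"test": "egger", "statistic": egger.intercept, "p": egger.p,
             "detail": f"intercept_se={egger.intercept_se:.4f}" if egger.computable else "not computable"},
            {"test": "begg", "statistic": begg.kendall_tau, "p": begg.p,
             "detail": "tau-b" if begg.computable else "not computable"},
        ]
        if len(effects) >= 3:
            tf = trim_and_fill(effects)
            bias_rows.append(
                {"test": "trim_and_fill", "statistic": float(tf.k0), "p": math.nan,
                 "detail": (
                     f"side={tf.side}; adjusted={tf.adjusted_ratio[0]:.4f}; "
                     f"original={tf.original_ratio[0]:.4f}"
                 )}
            )
        pd.DataFrame(bias_rows).to_csv(odir / "bias_tests.csv", index=False)

        ba = bland_altman_fe_re(lt_fe, lt_re)
        ba.table.assign(mean_diff=ba.mean_diff, limit_low=ba.limits[0],
                        limit_high=ba.limits[1]).to_csv(
            odir / "bland_altman.csv", index=False
        )

        if config.loo:
            leave_one_out(network, spec_re).to_csv(
                odir / "leave_one_out.csv", index=False
            )

        tau = fit_re.heterogeneity_sd
        log_lines.append(
            f"{outcome_id}: trials={network.n_trials} "
            f"psrf_max={max(conv.psrf.values()):.4f} "
            f"tau_median={float(np.median(tau)) if tau is not None else 0.0:.4f} "
            f"dic_consistency={dic_c:.2f} dic_ume={dic_u:.2f} "
            f"elapsed={time.time() - t0:.1f}s"
        )

    log_lines.append(f"total elapsed = {time.time() - t_start:.1f}s")
    if flagged:
        log_lines.append(f"CONVERGENCE FLAGGED for outcomes: {', '.join(flagged)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {"flagged": bool(flagged), "flagged_outcomes": flagged, "out_dir": str(out)}
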