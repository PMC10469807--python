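# Methods

## Evidence model

The unit of analysis is a two-arm randomized trial. The package supports
exactly the two data shapes that published oncology trial reports
provide:

* **Contrast-level records** for time-to-event outcomes: a hazard ratio
  with a 95% CI. These are converted once, at load time, to
  `y_i = ln HR` with standard error
  `s_i = (ln U − ln L) / (2 z)`, `z = 1.959964`. The unrounded normal
  quantile is used so derived SEs are reproducible to four decimals.
  The HR point estimate need not be the geometric mean of its CI (some
  published intervals are asymmetric on the log scale); only the CI
  width informs the SE.
* **Arm-level records** for binary outcomes: an arm size `n` and an
  event percentage. Event counts are reconstructed as
  `round(pct × n / 100)` with ties rounded to even. Intention-to-treat
  arm sizes are used as denominators throughout, including for safety
  outcomes whose true safety-population denominators are not published;
  the induced error is below one event per arm.

A network for one outcome is a connected graph of treatments with one
edge per directly compared pair, counted per trial. Construction
validates connectivity (naming the isolated component on failure),
uniqueness of (trial, outcome) records, and two-arm structure. The
12-trial ALK evidence base ships as packaged CSVs in the same dialects
the loaders accept, so bundled and user data are interchangeable. The
discontinuation outcome covers 11 trials (one trial reported no data);
one trial's discontinuation percentages are transcribed as printed in
the source despite being implausible against the trial's own report —
they are flagged in `alknma.fixtures.FLAGGED_ROWS` rather than edited,
because the package's contract is to analyze the tables as published.

## Bayesian NMA

Basic parameters `d_k` express each treatment's log relative effect
versus a reference; all pairwise contrasts are differences of basic
parameters, so the consistency assumption is structural rather than
enforced by penalty. Likelihoods:

* contrast: `y_i ~ Normal(delta_i, s_i^2)`
* binary: `r_ik ~ Binomial(n_ik, p_ik)`, `logit p = mu_i` (control) or
  `mu_i + delta_i` (experimental)

with `delta_i ~ Normal(d_alt − d_ref, tau^2)` under random effects or
`delta_i = d_alt − d_ref` under fixed effects.

**Priors.** `d_k ~ Normal(0, 10^2)` and `mu_i ~ Normal(0, 10^2)` are
vague on the log scale. `tau ~ Uniform(0, U)` with `U = 2` for log-HR
outcomes and `U = 5` for log-OR outcomes — both far above any plausible
between-trial SD for these endpoints, following common BUGS/gemtc
practice; `U` is configurable per fit.

**Sampler.** Metropolis-within-Gibbs, vectorized across chains:

* contrast trial effects `delta` and (given the trial effects) the basic
  parameters `d` have normal full conditionals and are drawn exactly;
* binomial-logit blocks (`mu`, `delta` for arm data) and `tau` use
  per-parameter Gaussian random-walk Metropolis steps;
* proposal scales adapt toward a 0.44 acceptance rate during burn-in
  only, so the kept chain is a fixed-kernel Markov chain;
* defaults: 4 chains, 10,000 burn-in, 50,000 kept iterations, thin 2
  (25,000 stored draws per chain). A thinning factor of 2 is used
  because thinning must be integral.

Chains start overdispersed: chain *c* offsets all basic parameters by
(−2, −0.5, +0.5, +2) × prior SD × 0.1 and spaces `tau` across its prior
range. All randomness flows through one seeded generator with a
documented draw order (trial effects, baselines, basic effects,
heterogeneity SD per sweep), so a seed reproduces draws bit for bit.

**Convergence.** Split-chain potential scale reduction factors and
effective sample sizes are computed via ArviZ for every basic parameter
and `tau`; a fit with any PSRF ≥ 1.05 is returned flagged with a warning
and reported with a prominent flag (and nonzero CLI exit), never
silently accepted. At default settings all bundled-outcome fits pass
with PSRF below 1.01.

**Summaries.** League-table point estimates and credible intervals are
quantiles of the log-contrast draws, exponentiated — this makes the
reciprocal identity `entry(a,b) = 1/entry(b,a)` exact, including for the
even-sample median. The Bayesian p-value attached to each cell is the
two-sided posterior tail probability `2 · min(Pr(>0), Pr(<0))`, with
0.05 as the significance threshold for table bolding. DIC is computed
from the residual-deviance trace as `Dbar + pD` with
`pD = Dbar − D(posterior means of the trial-level parameters)`.

## Ranking

Per draw, treatments are ordered by their basic effect — ascending when
lower values are better (hazards, adverse-event odds), descending for
response odds — and rank probabilities are frequencies over draws. SUCRA
is the mean of the cumulative rank probabilities over the first K−1
ranks; it averages exactly 0.5 across treatments, which the test suite
asserts as an identity. Exact ties (possible only against the
reference's zero effect, a measure-zero event for continuous draws)
break by fixed treatment order via a stable sort. SUCRA is reported as a
percentage to 2 decimals.

## Inconsistency assessment

* **Node-splitting** (local): an edge lying on a cycle gets its own
  direct parameter while the remaining trials inform the indirect
  contrast through the basic parameters; the Bayesian p-value of the
  direct−indirect difference flags disagreement. Splittable edges are
  the non-bridge edges of the comparison graph. P-values are not
  multiplicity-adjusted.
* **UME model** (global): every observed comparison receives its own
  free parameter (edges oriented as in their first trial), sharing the
  likelihood machinery through a different design matrix; consistency is
  considered adequate when its DIC is no more than ~3 above the UME DIC.

## Pairwise meta-analysis

Inverse-variance fixed-effect pooling with Cochran's Q, and
DerSimonian–Laird random effects with
`tau^2 = max(0, (Q − df)/(Σw − Σw²/Σw))`. `I² = 100·max(0,(Q−df)/Q)`,
forced to 0 when `df = 0` (single-study comparisons carry a
"heterogeneity not estimable" flag instead of NaN). Per-trial odds
ratios use the Haldane–Anscombe correction (0.5 added to all four cells
only when a cell is zero); double-zero and double-full tables carry no
contrast information and are excluded with a warning. Plain
normal-theory CIs are used (no Knapp–Hartung adjustment, matching the
source analysis's conventions).

## Publication-bias diagnostics

Funnel points are comparison-adjusted: each study is centered on its own
direct comparison's fixed-effect pooled estimate, which makes funnel
asymmetry interpretable across a network. Contour boundaries are emitted
at two-sided p ∈ {0.10, 0.05, 0.01}. Egger's test regresses `y/se` on
`1/se` with a t-test on the intercept (n−2 df); Begg's test correlates
variance-stabilized deviates with variances using tie-corrected Kendall
tau-b. Trim-and-fill iterates fixed-effect trimming with the rank-based
L0 estimator by default (R0 available), imputes mirror-image studies
about the final trimmed pool, and reports a DerSimonian–Laird re-pool of
observed plus imputed studies. The imputation side is chosen
automatically by the sign of the rank-sum asymmetry statistic of the
centered effects. These diagnostics are applied to the pooled
experimental-vs-control effect sets across comparisons, the standard
choice when individual comparisons have too few studies.

## Sensitivity analyses

Leave-one-out refits the NMA once per excluded trial, reporting each
surviving pairwise contrast; exclusions that disconnect the network or
drop a treatment are reported in-table rather than raised. Refits use
the primary seed plus a trial-id-derived offset for reproducibility.
FE-vs-RE agreement is summarized Bland–Altman style on log-scale league
medians (mean difference ± 1.96 SD limits). The brain-metastasis
subgroup is handled as a separate outcome network rather than a
covariate model, mirroring how the trials report it.

## Synthetic data

The generator draws from exactly the model the engine fits: trial
effects `Normal(d_alt − d_ref, tau²)`, observed either with a configured
contrast SE or as binomial arms with `Normal(0, 0.1)` jitter on the
baseline logit. Topologies: `star`, `loop`, and `paper_like` (the
bundled network's exact 7-node, 12-trial edge multiset). Defaults mirror
the bundled data's scale: arm sizes ≈ 150, contrast SEs 0.1–0.3,
baseline event probability 0.4, between-trial SD 0.1. Because generator
and engine share one data model, passing recovery tests demonstrate
correctness of the machinery, not robustness to real-data pathologies
(non-proportional hazards, informative crossover, outcome-reporting
quirks), which the synthetic networks deliberately do not emulate.

## Test problem sizes

Unit tests run the sampler at 2 chains × a few thousand iterations,
which is ample for the small conjugate-dominated models they probe; the
end-to-end suite refits all six bundled outcomes at the full default
settings. Parameter-recovery coverage uses 50 replicates of the
paper-like topology at reduced draws (2 × 3,000 kept), sized so the
Monte-Carlo error of a 95% interval is well below the binomial tolerance
of the ≥ 90% coverage criterion.

## Known limitations

* Two-arm trials only; the contrast data model has no multi-arm
  correlation handling (the bundled network contains none).
* Survival outcomes enter through published HRs; no arm-based survival
  modelling or individual-patient reconstruction.
* The binomial-logit model conditions on reconstructed integer counts;
  percentages rounded in the source introduce ≤ 0.5-event quantization.
* Node-split and UME machinery assume the consistency fit's priors are
  appropriate for the expanded parameterizations.
* OS estimates inherit the crossover contamination of the underlying
  trials; the package quantifies, but cannot correct, such biases.
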