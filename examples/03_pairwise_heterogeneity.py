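"""Frequentist pairwise meta-analysis of every direct comparison.

DerSimonian-Laird random-effects pooling with Cochran's Q and I^2 per
comparison; I^2 above 50% flags high between-trial heterogeneity.
"""

from alknma import load_fixture
from alknma.pairwise import direct_comparisons

for outcome_id in ("pfs", "sae"):
    network = load_fixture(outcome_id)
    label = "HR" if network.outcome.data_kind == "contrast_loghr" else "OR"
    print(f"\n{outcome_id.upper()} direct comparisons (random effects):")
    for (ref, alt), res in direct_comparisons(network).items():
        lo, hi = res.ci95_ratio
        i2 = f"I2={res.i_squared:5.1f}%" if res.heterogeneity_estimable else "I2  n/a  "
        print(
            f"  {alt:<11} vs {ref:<13} {label} {res.pooled_ratio:5.2f} "
            f"({lo:.2f}, {hi:.2f})  k={res.n_studies}  {i2}"
        )

print(
    "\nThe crizotinib-vs-chemotherapy SAE comparison shows I2 near 80%: the "
    "three trials disagree far beyond chance, which motivates the "
    "random-effects model and the leave-one-out sensitivity analysis."
)
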