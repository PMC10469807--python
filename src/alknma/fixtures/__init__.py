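"""Bundled 12-trial ALK-inhibitor evidence base (printed trial summaries).

Seven treatments — six ALK inhibitors (crizotinib, alectinib, ceritinib,
brigatinib, lorlatinib, ensartinib) plus platinum-based chemotherapy —
compared head-to-head in 12 randomized phase III trials (n = 3169).

Outcomes:

=================  ============  ==========  =========================
outcome id         data kind     better      notes
=================  ============  ==========  =========================
pfs                contrast HR   lower       12 trials
os                 contrast HR   lower       12 trials
pfs_bm             contrast HR   lower       baseline brain-metastasis
                                             subgroup, 12 trials
orr                arm binary    higher      responder counts
sae                arm binary    lower       grade >= 3 adverse events
discontinuation    arm binary    lower       11 trials (PROFILE1007
                                             reported no data)
=================  ============  ==========  =========================

Event counts for the binary outcomes are reconstructed from the published
arm percentages and intention-to-treat arm sizes.  The CROWN
discontinuation percentages (63.76%/58.45%) are transcribed as printed in
the source tables even though they are implausibly high relative to the
trial report; see ``FLAGGED_ROWS``.
"""

from importlib import resources

from ..network import (
    EvidenceNetwork,
    OutcomeSpec,
    Treatment,
    build_network,
    read_arm_csv,
    read_contrast_csv,
)

__all__ = ["OUTCOMES", "TREATMENTS", "FLAGGED_ROWS", "load_fixture", "fixture_path"]

TREATMENTS = (
    Treatment("crizotinib", "Crizotinib"),
    Treatment("alectinib", "Alectinib"),
    Treatment("ceritinib", "Ceritinib"),
    Treatment("brigatinib", "Brigatinib"),
    Treatment("lorlatinib", "Lorlatinib"),
    Treatment("ensartinib", "Ensartinib"),
    Treatment("chemotherapy", "Chemotherapy"),
)

OUTCOMES = {
    "pfs": OutcomeSpec("pfs", "contrast_loghr", "lower"),
    "os": OutcomeSpec("os", "contrast_loghr", "lower"),
    "pfs_bm": OutcomeSpec("pfs_bm", "contrast_loghr", "lower"),
    "orr": OutcomeSpec("orr", "arm_binary", "higher"),
    "sae": OutcomeSpec("sae", "arm_binary", "lower"),
    "discontinuation": OutcomeSpec("discontinuation", "arm_binary", "lower"),
}

#: Rows transcribed as printed despite internal inconsistency in the source.
FLAGGED_ROWS = {
    ("CROWN", "discontinuation"): (
        "percentages 63.76/58.45 contradict the trial report's ~7%/9%; "
        "kept as printed"
    ),
}


def fixture_path(kind: str):
    """Path to a bundled CSV; ``kind`` is 'contrasts' or 'arms'."""
    name = {"contrasts": "alk_contrasts.csv", "arms": "alk_arms.csv"}[kind]
    return resources.files(__name__) / name


def load_fixture(outcome_id: str) -> EvidenceNetwork:
    """The bundled evidence network for one of the six outcomes."""
    if outcome_id not in OUTCOMES:
        raise KeyError(
            f"unknown outcome {outcome_id!r}; choose from {sorted(OUTCOMES)}"
        )
    outcome = OUTCOMES[outcome_id]
    if outcome.data_kind == "contrast_loghr":
        obs = read_contrast_csv(fixture_path("contrasts"), outcome_id)
    else:
        obs = read_arm_csv(fixture_path("arms"), outcome_id)
    present = {
        lab
        for o in obs
        for lab in (
            (o.treat_ref, o.treat_alt) if hasattr(o, "treat_ref") else (o.treatment,)
        )
    }
    treatments = [t for t in TREATMENTS if t.id in present]
    return build_network(obs, outcome, treatments=treatments)
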