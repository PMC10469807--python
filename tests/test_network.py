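"""Evidence-network construction, effect derivation, and fixture integrity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alknma import (
    ContrastObservation,
    OutcomeSpec,
    build_network,
    derive_log_hr,
    load_fixture,
    reconstruct_events,
)
from alknma.fixtures import OUTCOMES
from alknma.network import (
    DisconnectedNetworkError,
    read_network_csv,
    write_network_csv,
)

CONTRAST = OutcomeSpec("sim", "contrast_loghr", "lower")


def _obs(trial, ref, alt, y=-0.5, se=0.2, outcome="sim"):
    return ContrastObservation(trial, ref, alt, y, se, outcome)


class TestDeriveLogHr:
    @pytest.mark.parametrize(
        "hr, lo, hi, want_log, want_se",
        [
            (0.37, 0.26, 0.52, -0.9943, 0.1768),  # J-ALEX PFS row
            (1.0, 0.5, 2.0, 0.0, 0.3537),  # symmetric interval around 1
        ],
    )
    def test_published_hr_recovery(self, hr, lo, hi, want_log, want_se):
        log_effect, se = derive_log_hr(hr, lo, hi)
        assert log_effect == pytest.approx(want_log, abs=1e-4)
        assert se == pytest.approx(want_se, abs=1e-4)

    @pytest.mark.parametrize(
        "hr, lo, hi",
        [
            (0.5, 0.6, 0.7),  # hr below its own CI
            (0.5, 0.7, 0.6),  # inverted CI
            (0.5, 0.5, 0.5),  # zero width: SE undefined
            (-0.5, 0.1, 1.0),  # non-positive ratio
            (0.5, 0.0, 1.0),
        ],
    )
    def test_invalid_inputs_rejected(self, hr, lo, hi):
        with pytest.raises(ValueError):
            derive_log_hr(hr, lo, hi)

    @given(
        log_hr=st.floats(-2, 2),
        half_width=st.floats(0.01, 1.5),
        offset=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_reciprocal_scale_consistency(self, log_hr, half_width, offset):
        """Inverting the hazard ratio negates the log effect, same SE."""
        lo = math.exp(log_hr - half_width)
        hi = math.exp(log_hr + half_width)
        hr = math.exp(log_hr - half_width + 2 * half_width * offset)
        hr = min(max(hr, lo), hi)  # guard float rounding at the interval ends
        y, se = derive_log_hr(hr, lo, hi)
        y_inv, se_inv = derive_log_hr(1 / hr, 1 / hi, 1 / lo)
        assert y_inv == pytest.approx(-y, abs=1e-12)
        assert se_inv == pytest.approx(se, rel=1e-12)


class TestReconstructEvents:
    @pytest.mark.parametrize(
        "percent, n, want",
        [(92.23, 103, 95), (78.85, 104, 82), (0.0, 50, 0), (100.0, 7, 7), (50.0, 1, 0)],
    )
    def test_rounding(self, percent, n, want):
        # 50% of 1 is 0.5: ties round to even, hence 0
        assert reconstruct_events(percent, n) == want

    def test_out_of_range_percent(self):
        with pytest.raises(ValueError):
            reconstruct_events(101.0, 10)
        with pytest.raises(ValueError):
            reconstruct_events(-0.1, 10)

    @given(percent=st.floats(0, 100), n=st.integers(1, 2000))
    @settings(max_examples=200, deadline=None)
    def test_result_in_range(self, percent, n):
        assert 0 <= reconstruct_events(percent, n) <= n


class TestBuildNetwork:
    def test_single_trial(self):
        net = build_network([_obs("T1", "A", "B")], CONTRAST)
        assert len(net.treatments) == 2
        assert net.edges == {frozenset({"A", "B"}): 1}

    def test_disconnected_raises_naming_component(self):
        with pytest.raises(DisconnectedNetworkError, match="disconnected"):
            build_network([_obs("T1", "A", "B"), _obs("T2", "C", "D")], CONTRAST)

    def test_unknown_treatment_label(self):
        from alknma import Treatment

        with pytest.raises(KeyError, match="unknown treatment"):
            build_network(
                [_obs("T1", "A", "B")], CONTRAST, treatments=[Treatment("A")]
            )

    def test_duplicate_trial_outcome_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network([_obs("T1", "A", "B"), _obs("T1", "A", "B")], CONTRAST)

    def test_edge_counts_accumulate(self):
        net = build_network(
            [_obs("T1", "A", "B"), _obs("T2", "A", "B"), _obs("T3", "B", "C")],
            CONTRAST,
        )
        assert net.edges[frozenset({"A", "B"})] == 2
        assert net.n_trials == 3


class TestFixture:
    def test_pfs_topology(self):
        net = load_fixture("pfs")
        assert len(net.treatments) == 7
        assert net.n_trials == 12
        want = {
            frozenset({"chemotherapy", "crizotinib"}): 3,
            frozenset({"chemotherapy", "alectinib"}): 1,
            frozenset({"chemotherapy", "ceritinib"}): 2,
            frozenset({"crizotinib", "alectinib"}): 3,
            frozenset({"crizotinib", "brigatinib"}): 1,
            frozenset({"crizotinib", "lorlatinib"}): 1,
            frozenset({"crizotinib", "ensartinib"}): 1,
        }
        assert net.edges == want

    @pytest.mark.parametrize("outcome_id", sorted(OUTCOMES))
    def test_all_outcomes_connected_with_seven_treatments(self, outcome_id):
        net = load_fixture(outcome_id)
        assert len(net.treatments) == 7  # connectivity certified by build

    def test_trial_counts(self):
        assert load_fixture("pfs").n_trials == 12
        assert load_fixture("discontinuation").n_trials == 11  # PROFILE1007 missing
        assert len(load_fixture("orr").observations) == 24

    def test_discontinuation_omits_profile1007(self):
        assert "PROFILE1007" not in load_fixture("discontinuation").trial_ids

    def test_unknown_outcome(self):
        with pytest.raises(KeyError):
            load_fixture("nonexistent")


class TestRoundTrip:
    @pytest.mark.parametrize("outcome_id", ["pfs", "orr"])
    def test_csv_round_trip(self, tmp_path, outcome_id):
        net = load_fixture(outcome_id)
        path = tmp_path / "net.csv"
        write_network_csv(net, path)
        back = read_network_csv(path, net.outcome)
        assert back.treatment_ids == net.treatment_ids
        assert back.edges == net.edges
        for a, b in zip(back.observations, net.observations):
            if outcome_id == "pfs":
                assert a.log_effect == pytest.approx(b.log_effect, rel=1e-9)
                assert a.se == pytest.approx(b.se, rel=1e-9)
            else:
                assert a == b
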