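"""NMA engine: conjugate limits, determinism, consistency structure, DIC."""

import math

import numpy as np
import pytest

from alknma import (
    ContrastObservation,
    NmaModelSpec,
    OutcomeSpec,
    build_network,
    compute_dic,
    fit_nma,
    gelman_rubin,
    league_table,
    pool_fixed,
)
from alknma.mcmc import RawDraws
from alknma.nma import PosteriorSamples
from alknma.simulate import SyntheticConfig, generate_binary_network, generate_contrast_network

CONTRAST = OutcomeSpec("sim", "contrast_loghr", "lower")
FAST = dict(chains=2, burn_in=500, kept_iterations=3000, thin=2)


def single_trial_network(y=-0.5, se=0.1):
    obs = [ContrastObservation("T1", "A", "B", y, se, "sim")]
    return build_network(obs, CONTRAST)


class TestFitNma:
    def test_single_trial_fixed_conjugate_limit(self):
        """With a vague prior, the FE posterior is ~N(y, se^2)."""
        net = single_trial_network()
        fit = fit_nma(net, NmaModelSpec(effect_model="fixed", seed=3, **FAST))
        d = fit.basic_effect_draws("B")
        assert d.mean() == pytest.approx(-0.5, abs=0.01)
        assert d.std() == pytest.approx(0.1, rel=0.05)

    def test_fixed_fit_matches_inverse_variance_pool(self):
        obs = [
            ContrastObservation("T1", "A", "B", -0.8, 0.2, "sim"),
            ContrastObservation("T2", "A", "B", -0.4, 0.3, "sim"),
            ContrastObservation("T3", "A", "B", -0.6, 0.25, "sim"),
        ]
        net = build_network(obs, CONTRAST)
        fit = fit_nma(net, NmaModelSpec(effect_model="fixed", seed=4, **FAST))
        pooled = pool_fixed([(o.log_effect, o.se) for o in obs])
        d = fit.basic_effect_draws("B")
        assert d.mean() == pytest.approx(pooled.pooled_log_effect, abs=0.02)
        assert d.std() == pytest.approx(pooled.pooled_se, rel=0.1)

    def test_seed_determinism_bit_identical(self, pfs_network, fast_spec):
        a = fit_nma(pfs_network, fast_spec, check_convergence=False)
        b = fit_nma(pfs_network, fast_spec, check_convergence=False)
        np.testing.assert_array_equal(a.raw.beta, b.raw.beta)
        np.testing.assert_array_equal(a.raw.tau, b.raw.tau)
        np.testing.assert_array_equal(a.raw.deviance, b.raw.deviance)

    def test_different_seed_different_draws(self, pfs_network, fast_spec):
        a = fit_nma(pfs_network, fast_spec, check_convergence=False)
        b = fit_nma(pfs_network, fast_spec.with_(seed=fast_spec.seed + 1),
                    check_convergence=False)
        assert not np.array_equal(a.raw.beta, b.raw.beta)

    def test_consistency_identity_per_draw(self, pfs_fast_fit):
        """d_AB + d_BC = d_AC holds exactly in every draw, by construction."""
        ab = pfs_fast_fit.contrast_draws("alectinib", "crizotinib")
        bc = pfs_fast_fit.contrast_draws("crizotinib", "chemotherapy")
        ac = pfs_fast_fit.contrast_draws("alectinib", "chemotherapy")
        np.testing.assert_allclose(ab + bc, ac, atol=1e-12)

    def test_reference_invariance_of_contrasts(self, pfs_network, fast_spec):
        fit_a = fit_nma(pfs_network, fast_spec, check_convergence=False)
        fit_b = fit_nma(
            pfs_network,
            fast_spec.with_(reference="chemotherapy", seed=fast_spec.seed + 5),
            check_convergence=False,
        )
        for pair in [("alectinib", "crizotinib"), ("lorlatinib", "ensartinib")]:
            med_a = np.median(fit_a.contrast_draws(*pair))
            med_b = np.median(fit_b.contrast_draws(*pair))
            assert med_a == pytest.approx(med_b, abs=0.05)

    def test_draw_count_contract(self, pfs_fast_fit, fast_spec):
        c, d, p = pfs_fast_fit.raw.beta.shape
        assert c == fast_spec.chains
        assert d == fast_spec.kept_iterations // fast_spec.thin
        assert p == 6
        assert np.all(pfs_fast_fit.heterogeneity_sd >= 0)

    def test_binary_model_recovers_single_trial_log_or(self):
        cfg = SyntheticConfig(
            n_treatments=2, topology="star", true_basic_effects=(0.0, 1.0),
            heterogeneity_sd=0.0, trials_per_edge=1, arm_size=4000, seed=9,
        )
        net = generate_binary_network(cfg)
        fit = fit_nma(
            net, NmaModelSpec(effect_model="fixed", reference="t1", seed=10, **FAST)
        )
        d = fit.basic_effect_draws("t2")
        assert np.median(d) == pytest.approx(1.0, abs=0.15)

    def test_unknown_reference_rejected(self, pfs_network):
        with pytest.raises(KeyError):
            fit_nma(pfs_network, NmaModelSpec(reference="nivolumab", **FAST))


class TestLeagueTable:
    def test_reciprocal_and_diagonal(self, pfs_fast_fit):
        table = league_table(pfs_fast_fit)
        k = len(table.treatments)
        np.testing.assert_allclose(np.diag(table.median), 1.0)
        np.testing.assert_allclose(table.median * table.median.T, np.ones((k, k)),
                                   rtol=1e-12)
        # CI bounds swap and invert across the diagonal
        np.testing.assert_allclose(table.low * table.high.T, np.ones((k, k)), rtol=1e-12)
        assert table.scale == "hr"

    def test_bayes_p_symmetric(self, pfs_fast_fit):
        table = league_table(pfs_fast_fit)
        np.testing.assert_allclose(table.bayes_p, table.bayes_p.T, atol=1e-12)


class TestGelmanRubin:
    @staticmethod
    def _wrap(chains: np.ndarray) -> PosteriorSamples:
        c, d = chains.shape
        raw = RawDraws(
            beta=chains[:, :, None], tau=None,
            delta=np.zeros((c, d, 1)), mu=None, deviance=np.zeros((c, d)),
        )
        return PosteriorSamples(
            param_names=("x",), treatments=("A", "x"), reference="A",
            trial_ids=("T1",), raw=raw, spec=NmaModelSpec(),
            data_kind="contrast_loghr",
        )

    @staticmethod
    def oracle_split_psrf(chains: np.ndarray) -> float:
        """Classic split-chain potential scale reduction factor."""
        c, d = chains.shape
        half = d // 2
        split = chains[:, : 2 * half].reshape(c * 2, half)
        m, n = split.shape
        means = split.mean(axis=1)
        w = split.var(axis=1, ddof=1).mean()
        b = n * means.var(ddof=1)
        var_plus = (n - 1) / n * w + b / n
        return math.sqrt(var_plus / w)

    def test_identical_iid_chains_near_one(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 2000))
        report = gelman_rubin(self._wrap(chains))
        assert report.psrf["d.x"] == pytest.approx(1.0, abs=0.01)
        assert report.passed

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        report = gelman_rubin(self._wrap(chains))
        assert report.psrf["d.x"] > 1.1
        assert not report.passed

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(4)
        chains = np.cumsum(rng.standard_normal((2, 500)), axis=1) * 0.05
        report = gelman_rubin(self._wrap(chains))
        assert report.psrf["d.x"] == pytest.approx(self.oracle_split_psrf(chains), rel=0.02)

    def test_requires_two_chains(self):
        s = self._wrap(np.zeros((2, 100)))
        s.raw.beta = s.raw.beta[:1]
        with pytest.raises(ValueError):
            gelman_rubin(s)


class TestDic:
    def test_single_trial_fixed_pd_near_one(self):
        net = single_trial_network(se=0.1)
        fit = fit_nma(net, NmaModelSpec(effect_model="fixed", seed=5, **FAST))
        dbar, pd_, dic = fit_nma, None, None
        dbar, pd_, dic = compute_dic(fit, net)
        assert pd_ == pytest.approx(1.0, abs=0.2)  # one free parameter
        assert dic == pytest.approx(dbar + pd_)

    def test_well_specified_dbar_near_data_points(self):
        cfg = SyntheticConfig(
            n_treatments=4, topology="star",
            true_basic_effects=(0.0, -0.5, -1.0, 0.3),
            heterogeneity_sd=0.0, trials_per_edge=4, contrast_se=0.2, seed=6,
        )
        net = generate_contrast_network(cfg)
        fit = fit_nma(net, NmaModelSpec(effect_model="fixed", seed=7, **FAST))
        n = len(net.observations)
        dbar, _, _ = compute_dic(fit, net)
        assert 0.4 * n < dbar < 1.8 * n
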