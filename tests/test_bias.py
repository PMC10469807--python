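"""Funnel diagnostics: Egger, Begg, trim-and-fill, comparison adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alknma import begg_test, comparison_adjusted_funnel, egger_test, load_fixture, trim_and_fill
from alknma.bias import contour_rays, network_effects
from alknma.pairwise import pool_fixed


def symmetric_effects(center=-0.5, k=4):
    """Mirrored pairs about the center, equal SEs: a perfectly symmetric funnel."""
    effects = []
    for i in range(1, k + 1):
        se = 0.1 + 0.05 * i
        effects.append((center + 0.2 * i, se))
        effects.append((center - 0.2 * i, se))
    return effects


class TestFunnel:
    def test_single_comparison_centering(self):
        net = load_fixture("pfs")
        points = comparison_adjusted_funnel(net)
        assert len(points) == 12
        by_pair = {}
        for p in points:
            by_pair.setdefault(p.comparison, []).append(p)
        assert len(by_pair) == 7
        # within each comparison, inverse-variance weighted centered effects sum to 0
        for pts in by_pair.values():
            w = np.array([1 / p.se**2 for p in pts])
            c = np.array([p.centered_effect for p in pts])
            assert float(w @ c) == pytest.approx(0.0, abs=1e-9)

    def test_contour_rays_levels(self):
        rays = contour_rays(0.5)
        assert set(rays["level"]) == {0.10, 0.05, 0.01}
        # stricter levels sit further out
        outer = rays[(rays.level == 0.01) & (rays.side == "right") & (rays.se == 0.5)]
        inner = rays[(rays.level == 0.10) & (rays.side == "right") & (rays.se == 0.5)]
        assert outer["effect"].iloc[0] > inner["effect"].iloc[0]


class TestEgger:
    def test_symmetric_set_null(self):
        res = egger_test(symmetric_effects())
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_too_few_studies_flagged(self):
        res = egger_test([(-0.5, 0.2), (0.1, 0.3)])
        assert not res.computable
        assert math.isnan(res.p)

    def test_detects_small_study_effect(self):
        # effects drift with se: classic small-study asymmetry
        effects = [(-0.2 - 2.0 * se, se) for se in np.linspace(0.05, 0.6, 10)]
        res = egger_test(effects)
        assert res.p < 0.05

    def test_fixture_pfs_asymmetry(self):
        # the PFS funnel is asymmetric (small trials report stronger benefit)
        effects = [(y, s) for _, y, s in network_effects(load_fixture("pfs"))]
        assert egger_test(effects).p < 0.10


def oracle_kendall(x, y):
    """Exhaustive pairwise concordance count with tie correction (tau-b)."""
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = (n0 - tx) * (n0 - ty)
    if denom == 0:  # one of the vectors is fully tied: tau undefined
        return math.nan
    return (concordant - discordant) / math.sqrt(denom)


class TestBegg:
    def test_perfect_concordance(self):
        effects = [(0.1 * i, 0.1 + 0.1 * i) for i in range(1, 6)]
        res = begg_test(effects)
        assert res.kendall_tau == pytest.approx(1.0)

    def test_too_few_studies(self):
        assert not begg_test([(0.1, 0.2), (0.2, 0.3)]).computable

    @given(
        data=st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)), min_size=3, max_size=30
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_tau_matches_exhaustive_count(self, data):
        res = begg_test(data)
        y = np.array([d[0] for d in data])
        s = np.array([d[1] for d in data])
        pooled = pool_fixed(data)
        deviate = (y - pooled.pooled_log_effect) / np.sqrt(
            np.maximum(s**2 - pooled.pooled_se**2, 1e-12)
        )
        want = oracle_kendall(list(deviate), list(s**2))
        if math.isnan(want):
            assert math.isnan(res.kendall_tau)
        else:
            assert res.kendall_tau == pytest.approx(want, abs=1e-9)

    def test_null_distribution_is_calibrated(self):
        # effects independent of variance: p should not concentrate near 0
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(50):
            se = rng.uniform(0.1, 0.5, size=12)
            y = rng.normal(-0.3, 0.25, size=12)
            if begg_test(list(zip(y, se))).p < 0.05:
                rejections += 1
        assert rejections <= 8  # ~5% nominal; allows binomial slack


class TestTrimFill:
    def test_symmetric_set_identity(self):
        effects = symmetric_effects()
        res = trim_and_fill(effects)
        assert res.k0 == 0
        assert res.adjusted_pooled[0] == pytest.approx(res.original_pooled[0], abs=1e-9)

    def test_suppressed_side_recovered(self):
        # start symmetric around -0.5, delete the 3 largest (right side):
        # trim-and-fill should impute on the right and move the pool upward
        effects = symmetric_effects(center=-0.5, k=5)
        effects.sort(key=lambda e: e[0])
        censored = effects[:-3]
        res = trim_and_fill(censored)
        assert res.side == "right"
        assert res.k0 >= 2
        assert res.adjusted_pooled[0] > res.original_pooled[0]
        # imputed studies mirror retained ones: all on the deleted side
        assert all(y > res.original_pooled[0] for y, _ in res.imputed)

    def test_estimators_agree_on_clear_case(self):
        effects = symmetric_effects(center=0.0, k=6)
        effects.sort(key=lambda e: e[0])
        censored = effects[:-4]
        l0 = trim_and_fill(censored, estimator="L0")
        r0 = trim_and_fill(censored, estimator="R0")
        assert abs(l0.k0 - r0.k0) <= 2

    def test_needs_three_studies(self):
        with pytest.raises(ValueError):
            trim_and_fill([(0.1, 0.2), (0.2, 0.2)])
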