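"""Provider decision model: decision rules, region partition, welfare identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import carebundle as cb
from carebundle.theory import _decide_bundled_vec, _decide_itemized_vec


def bundled(P):
    return cb.PaymentScheme.bundled(P)


def itemized(p1, p2):
    return cb.PaymentScheme.itemized(p1, p2)


class TestDecisions:
    @pytest.mark.parametrize(
        "c1,c2,s,P,choice,pi12",
        [
            (0.4, 0.5, 0.2, 0.8, "both", 0.1),
            (1.0, 1.0, 0.0, 1.5, "none", -0.5),
            (0.5, 0.5, 0.0, 1.0, "none", 0.0),  # zero profit resolves to none
        ],
    )
    def test_bundled_rule(self, c1, c2, s, P, choice, pi12):
        d = cb.decide_bundled(cb.CostProfile(c1, c2, s), bundled(P))
        assert d.choice == choice
        assert d.pi12 == pytest.approx(pi12)
        assert (d.pi1, d.pi2) == (-c1, -c2)  # partial provision earns nothing

    @pytest.mark.parametrize(
        "c1,c2,s,p1,p2,choice",
        [
            (0.3, 2.0, 0.1, 0.5, 1.0, "only1"),
            (0.4, 0.9, 0.1, 0.5, 1.0, "both"),
            (5.0, 5.0, 0.0, 1.0, 1.0, "none"),
        ],
    )
    def test_itemized_rule(self, c1, c2, s, p1, p2, choice):
        d = cb.decide_itemized(cb.CostProfile(c1, c2, s), itemized(p1, p2))
        assert d.choice == choice

    def test_itemized_both_profit(self):
        d = cb.decide_itemized(cb.CostProfile(0.4, 0.9, 0.1), itemized(0.5, 1.0))
        assert d.pi12 == pytest.approx(0.3)

    def test_negative_synergy_rejected(self):
        with pytest.raises(ValueError, match="synergy"):
            cb.CostProfile(0.5, 0.5, -0.1)

    def test_scheme_mode_mismatch(self):
        with pytest.raises(ValueError):
            cb.decide_bundled(cb.CostProfile(0.1, 0.1), itemized(1, 1))

    @given(
        c1=st.floats(0.01, 3.0),
        c2=st.floats(0.01, 3.0),
        s=st.floats(0.0, 0.5),
        p1=st.floats(0.1, 1.5),
        p2=st.floats(0.1, 1.5),
    )
    def test_itemized_matches_inequalities(self, c1, c2, s, p1, p2):
        """Off boundaries, the profit argmax reproduces the analytic decision rules."""
        d = cb.decide_itemized(cb.CostProfile(c1, c2, s), itemized(p1, p2))
        if c1 < p1 and c2 > p2 + s:
            assert d.choice == "only1"
        if c2 < p2 and c1 > p1 + s:
            assert d.choice == "only2"
        if c1 < p1 + s and c2 < p2 + s and p1 + p2 - c1 - c2 + s > 0:
            # both is feasible; it must beat the singles given the first two fail
            if not (c2 < p2 and c1 > p1 + s) and not (c1 < p1 and c2 > p2 + s):
                assert d.choice == "both"


class TestRegions:
    @pytest.mark.parametrize(
        "c1,c2,s,p1,p2,region",
        [
            (0.3, 1.05, 0.0, 0.5, 1.0, "A"),
            (0.3, 2.0, 0.0, 0.5, 1.0, "C"),
            (0.1, 0.1, 0.0, 0.5, 1.0, "both_both"),
            (5.0, 5.0, 0.0, 0.5, 1.0, "none_none"),
        ],
    )
    def test_examples(self, c1, c2, s, p1, p2, region):
        assert cb.classify_region(cb.CostProfile(c1, c2, s), p1, p2) == region

    def test_boundary_is_degenerate(self):
        assert cb.classify_region(cb.CostProfile(0.5, 2.0, 0.0), 0.5, 1.0) == "degenerate"

    def test_region_agrees_with_decision_cross_tab(self):
        """Oracle: regions are exactly the cross-tabulation of the two schemes."""
        rng = np.random.default_rng(5)
        p1, p2, s = 0.6, 0.9, 0.15
        for c1, c2 in rng.uniform(0, 2, size=(300, 2)):
            cost = cb.CostProfile(c1, c2, s)
            region = cb.classify_region(cost, p1, p2)
            it = cb.decide_itemized(cost, itemized(p1, p2)).choice
            bu = cb.decide_bundled(cost, bundled(p1 + p2)).choice
            expected = {
                ("only1", "both"): "A", ("only2", "both"): "B",
                ("only1", "none"): "C", ("only2", "none"): "D",
                ("both", "both"): "both_both", ("none", "none"): "none_none",
            }[(it, bu)]
            assert region == expected


class TestNesting:
    def test_itemized_both_implies_bundled_both(self):
        """At P = p1 + p2 and s >= 0, the bundled scheme nests itemized joint provision."""
        rng = np.random.default_rng(17)
        n = 100_000
        c1, c2 = rng.uniform(0, 3, n), rng.uniform(0, 3, n)
        p1, p2, s = rng.uniform(0.2, 1.5, 3)
        it = _decide_itemized_vec(c1, c2, s, p1, p2)
        bu = _decide_bundled_vec(c1, c2, s, p1 + p2)
        assert not ((it == 3) & (bu != 3)).any()

    def test_bundled_share_monotone_in_price_and_synergy(self):
        base = cb.region_area_uniform(0.5, 0.5, 0.0, (0, 1, 0, 1))["bundled_both"]
        for p1, p2, s in [(0.6, 0.5, 0.0), (0.5, 0.5, 0.2), (0.7, 0.7, 0.3)]:
            area = cb.region_area_uniform(p1, p2, s, (0, 1, 0, 1))["bundled_both"]
            assert area >= base


class TestAreasAndSimulation:
    def test_closed_form_areas(self):
        a = cb.region_area_uniform(0.5, 0.5, 0.0, (0, 1, 0, 1))
        assert a["bundled_both"] == pytest.approx(0.5, abs=1e-12)
        assert a["itemized_both"] == pytest.approx(0.25, abs=1e-12)
        # corner-cut square: 0.7^2 minus the triangle above c1+c2 = 1.2
        a2 = cb.region_area_uniform(0.5, 0.5, 0.2, (0, 1, 0, 1))
        assert a2["itemized_both"] == pytest.approx(0.47, abs=1e-9)

    def test_bundled_share_with_synergy(self):
        pop = cb.PopulationSpec(family="uniform", params={"upper": (1, 1)}, n_providers=400_000, seed=2)
        comp = cb.simulate_population(pop, bundled(1.0), itemized(0.5, 0.5),
                                      cb.BenefitProfile(1, 1, 2), s=0.25)
        exact = 1 - 0.75**2 / 2  # area of {c1 + c2 < 1.25} in the unit square
        se = np.sqrt(exact * (1 - exact) / pop.n_providers)
        assert abs(comp.shares["bundled"]["both"] - exact) < 3 * se

    def test_shares_sum_to_one(self):
        pop = cb.PopulationSpec(family="lognormal",
                                params={"lower": (0.1, 0.1), "mu": (-1, -0.5), "sigma": (0.6, 0.6)},
                                n_providers=50_000, seed=4)
        comp = cb.simulate_population(pop, bundled(1.2), itemized(0.6, 0.6),
                                      cb.BenefitProfile(1, 1, 2), s=0.1)
        for scheme in ("bundled", "itemized"):
            assert sum(comp.shares[scheme].values()) == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_matches_polygon_areas(self):
        """Region shares from simulation agree with exact clipping within 3 binomial SEs."""
        p1, p2, s = 0.5, 1.0, 0.15
        n = 1_000_000
        pop = cb.PopulationSpec(family="uniform", params={"upper": (2, 2)}, n_providers=n, seed=9)
        comp = cb.simulate_population(pop, bundled(p1 + p2), itemized(p1, p2),
                                      cb.BenefitProfile(1, 1, 2), s=s)
        areas = cb.region_area_uniform(p1, p2, s, (0, 2, 0, 2))
        for region in ("A", "B", "C", "D", "both_both", "none_none"):
            exact = areas[region]
            se = np.sqrt(max(exact * (1 - exact), 1e-12) / n)
            assert abs(comp.region_shares[region] - exact) <= 3 * se + 1e-9, region

    def test_unsupported_family(self):
        pop = cb.PopulationSpec(family="cauchy", params={}, n_providers=10, seed=0)
        with pytest.raises(ValueError, match="family"):
            cb.simulate_population(pop, bundled(1), itemized(0.5, 0.5), cb.BenefitProfile(1, 1, 2))

    def test_unbounded_support_rejected(self):
        with pytest.raises(ValueError, match="bounded"):
            cb.region_area_uniform(0.5, 0.5, 0.0, (0, np.inf, 0, 1))


class TestWelfare:
    """Symmetric population with equal mass in regions A/B/C/D, p1 = p2."""

    @staticmethod
    def _population(p1=0.5, p2=0.5):
        # one point per comparison region, equal weights
        pts = [(0.2, 0.7), (0.7, 0.2), (0.2, 2.0), (2.0, 0.2)]  # A, B, C, D
        for (c1, c2), want in zip(pts, ("A", "B", "C", "D")):
            assert cb.classify_region(cb.CostProfile(c1, c2, 0.0), p1, p2) == want
        return cb.PopulationSpec(family="points", params={"points": pts}, n_providers=4)

    def test_equal_spending(self):
        pop = self._population()
        comp = cb.simulate_population(pop, bundled(1.0), itemized(0.5, 0.5),
                                      cb.BenefitProfile(1, 1, 2), s=0.0)
        assert abs(comp.spending["bundled"] - comp.spending["itemized"]) < 1e-6

    def test_benefit_equal_iff_no_synergy(self):
        pop = self._population()
        no_syn = cb.simulate_population(pop, bundled(1.0), itemized(0.5, 0.5),
                                        cb.BenefitProfile(1.0, 1.0, 2.0), s=0.0)
        assert no_syn.benefit["bundled"] == pytest.approx(no_syn.benefit["itemized"], abs=1e-12)
        syn = cb.simulate_population(pop, bundled(1.0), itemized(0.5, 0.5),
                                     cb.BenefitProfile(1.0, 1.0, 2.5), s=0.0)
        assert syn.benefit["bundled"] > syn.benefit["itemized"]
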