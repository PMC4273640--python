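"""Payoffs, the official's choice rule, and equilibrium enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oracles import brute_force_equilibria
from physioecon.game import (
    AgentPreferences,
    Bid,
    BudgetViolationError,
    DEFAULT_PARAMS,
    GameParams,
    PayoffVector,
    UndefinedBidError,
    apply_inspection,
    continuous_equilibrium_bribe,
    enumerate_equilibria,
    equilibria_to_frame,
    monetary_payoffs,
    official_choice,
    psych_equilibrium_bids,
    psychological_payoffs,
)


class TestMonetaryPayoffs:
    @pytest.mark.parametrize(
        "bid, expected",
        [
            (Bid(5, 5), (17.5, 12.5, 12.5)),  # symmetric profile
            (Bid(10, 0), (15.0, 25.0, 15.0)),  # bribe-free winner
        ],
    )
    def test_default_economy(self, bid, expected):
        p = monetary_payoffs(bid)
        assert (p.official, p.winner, p.loser) == expected

    def test_degenerate_economy_pays_endowment_plus_bribe(self):
        """With a = c = R = 0 the firms earn only the endowment while the
        official still pockets the (costless) bribe transfer."""
        params = GameParams(F=10, a=0, c=0, A=10, R=0)
        for b in range(11):
            p = monetary_payoffs(Bid(10 - b, b), params)
            assert (p.official, p.winner, p.loser) == (10 + b, 10, 10)

    def test_budget_violation_rejected(self):
        with pytest.raises(BudgetViolationError):
            monetary_payoffs(Bid(5, 4))
        with pytest.raises(BudgetViolationError):
            monetary_payoffs(Bid(11, -1))

    @given(
        b=hst.integers(0, 10),
        F=hst.floats(0, 50),
        a=hst.floats(0, 2),
        c=hst.floats(0, 5),
        R=hst.floats(0, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_payoff_identities(self, b, F, a, c, R):
        """Official - loser = bribe; winner - loser = R - c*B."""
        params = GameParams(F=F, a=a, c=c, A=10, R=R)
        p = monetary_payoffs(Bid(10 - b, b), params)
        assert p.official - p.loser == pytest.approx(b)
        assert p.winner - p.loser == pytest.approx(R - c * b)


class TestPsychologicalPayoffs:
    def test_gamma_zero_reduces_to_monetary_over_full_grid(self):
        prefs = AgentPreferences()
        for b in range(11):
            for role in (1, 2):
                mon = monetary_payoffs(Bid(10 - b, b), winner_role=role)
                psy = psychological_payoffs(
                    Bid(10 - b, b), prefs=prefs, winner_role=role
                )
                assert mon == psy

    def test_official_aversion_neutralizes_bribe(self):
        prefs = AgentPreferences(gamma_official=1.0)
        p = psychological_payoffs(Bid(5, 5), prefs=prefs)
        assert p.official == pytest.approx(12.5)  # F + a*Q only

    def test_winner_aversion_raises_bribe_cost(self):
        prefs = AgentPreferences(gamma_firm1=0.5)
        p = psychological_payoffs(Bid(5, 5), prefs=prefs, winner_role=1)
        assert p.winner == pytest.approx(10.0)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            AgentPreferences(gamma_official=-0.1)


def test_loser_payoff_independent_of_winner_bribe():
    """pi_loser = F + a*Q_w carries no bribe term: holding quality fixed
    and varying the bribe (via the budget) leaves the loser unchanged."""
    Q = 5
    for B in range(0, 6):
        params = GameParams(A=Q + B)
        p = monetary_payoffs(Bid(Q, B), params)
        assert p.loser == pytest.approx(params.F + params.a * Q)
        psy = psychological_payoffs(
            Bid(Q, B), params, AgentPreferences(0.3, 0.7, 0.2)
        )
        assert psy.loser == pytest.approx(params.F + params.a * Q)


class TestOfficialChoice:
    def test_bribe_averse_official_picks_quality(self):
        # a = 0.5 >= 1 - 0.6: quality branch
        p = official_choice(Bid(10, 0), Bid(5, 5), gamma_official=0.6)
        assert p == (1.0, 0.0)

    def test_monetary_official_picks_higher_score(self):
        # a*Q + B: 6.5 for (7,3) vs 7.0 for (6,4)
        p = official_choice(Bid(7, 3), Bid(6, 4), gamma_official=0.0)
        assert p == (0.0, 1.0)

    def test_identical_bids_split_uniformly(self):
        assert official_choice(Bid(5, 5), Bid(5, 5)) == (0.5, 0.5)

    def test_tie_rules(self):
        assert official_choice(Bid(5, 5), Bid(5, 5), tie_rule="firm1") == (1, 0)
        assert official_choice(Bid(5, 5), Bid(5, 5), tie_rule="firm2") == (0, 1)
        with pytest.raises(ValueError):
            official_choice(Bid(5, 5), Bid(5, 5), tie_rule="coin")

    def test_boundary_aversion_uses_quality_branch(self):
        # a = 1 - gamma exactly: the higher quality is chosen outright
        p = official_choice(Bid(10, 0), Bid(0, 10), gamma_official=0.5)
        assert p == (1.0, 0.0)


class TestEnumeration:
    def test_default_set_contains_printed_profiles(self):
        eqs = enumerate_equilibria()
        triples = {
            (p.bid_firm1.B, p.bid_firm2.B, p.strict) for p in eqs
        }
        assert (3, 3, True) in triples
        assert (4, 4, True) in triples
        assert (5, 5, False) in triples  # weak: deviating down ties payoff

    def test_symmetric_overbribing_profile_absent(self):
        eqs = enumerate_equilibria()
        bribes = {(p.bid_firm1.B, p.bid_firm2.B) for p in eqs}
        assert (2, 2) not in bribes  # deviation to B=3 wins outright

    @pytest.mark.parametrize(
        "gammas",
        [
            (0.0, 0.0, 0.0),
            (0.3, 0.0, 0.0),
            (0.0, 0.5, 0.0),
            (0.2, 0.4, 0.9),
            (0.7, 0.1, 0.1),  # quality branch official
        ],
    )
    def test_matches_bruteforce_oracle(self, gammas):
        go, g1, g2 = gammas
        eqs = enumerate_equilibria(
            gamma_official=go, firm_gammas=(g1, g2)
        )
        got = {
            (int(p.bid_firm1.B), int(p.bid_firm2.B), p.strict) for p in eqs
        }
        want = brute_force_equilibria(
            gamma_official=go, gamma_firm1=g1, gamma_firm2=g2
        )
        assert got == want

    def test_grid_refinement_converges_to_continuous_solution(self):
        """Symmetric equilibrium bribes live in [5 - 2(a+c)h/c, 5] for
        grid step h, collapsing onto the continuous B = R/c = 5."""
        prev_lo = -np.inf
        for k in (1, 2, 5, 10):
            step = 1.0 / k
            eqs = enumerate_equilibria(grid_step=step)
            sym = [
                p.bid_firm1.B
                for p in eqs
                if p.bid_firm1.B == p.bid_firm2.B
            ]
            assert sym, f"no symmetric equilibria at step {step}"
            lo, hi = min(sym), max(sym)
            assert hi == pytest.approx(5.0)
            assert lo >= 5.0 - 2.5 * step - 1e-9
            assert lo >= prev_lo  # band tightens monotonically
            prev_lo = lo

    def test_export_frame_columns(self):
        df = equilibria_to_frame(enumerate_equilibria())
        assert list(df.columns) == [
            "firm1_Q", "firm1_B", "firm2_Q", "firm2_B", "strict",
        ]
        assert len(df) >= 3


class TestPsychEquilibrium:
    def test_bribery_averse_official_kills_bribes(self):
        pred = psych_equilibrium_bids(
            prefs=AgentPreferences(gamma_official=0.6)
        )
        assert pred.branch == "quality"
        assert pred.bids[0] == Bid(10.0, 0.0)
        assert pred.bids[1] == Bid(10.0, 0.0)

    def test_neutral_agents_recover_continuous_solution(self):
        pred = psych_equilibrium_bids()
        assert pred.branch == "bribe"
        assert pred.bids[0].B == pytest.approx(5.0)
        assert continuous_equilibrium_bribe() == pytest.approx(5.0)

    def test_firm_aversion_lowers_bribe(self):
        pred = psych_equilibrium_bids(
            prefs=AgentPreferences(gamma_firm1=0.5)
        )
        assert pred.bids[0].B == pytest.approx(4.0)  # 10 / (2 + 0.5)
        assert pred.bids_integer[0] == Bid(6.0, 4.0)
        assert pred.bids[1].B == pytest.approx(5.0)

    def test_zero_cost_and_aversion_is_undefined(self):
        with pytest.raises(UndefinedBidError):
            psych_equilibrium_bids(GameParams(c=0.0))


class TestInspection:
    def test_revealed_bribe_zeroes_corrupt_pair(self):
        p = apply_inspection(monetary_payoffs(Bid(5, 5)), True, True)
        assert (p.official, p.winner, p.loser) == (0.0, 0.0, 12.5)

    def test_false_accusation_zeroes_loser(self):
        p = apply_inspection(monetary_payoffs(Bid(10, 0)), False, True)
        assert (p.official, p.winner, p.loser) == (15.0, 25.0, 0.0)

    def test_no_inspection_is_identity(self):
        base = monetary_payoffs(Bid(7, 3))
        assert apply_inspection(base, True, False) == base

    def test_inspection_never_profitable_in_expectation_for_loser(self):
        """For every winner bid and every belief about the bribe, the
        loser's expected payoff change from inspecting is <= 0."""
        for b in range(11):
            base = monetary_payoffs(Bid(10 - b, b))
            bribed = b > 0
            after = apply_inspection(base, bribed, True)
            delta_if_bribed = after.loser - base.loser if bribed else 0.0
            no_bribe_after = apply_inspection(
                monetary_payoffs(Bid(10, 0)), False, True
            )
            delta_if_clean = no_bribe_after.loser - monetary_payoffs(
                Bid(10, 0)
            ).loser
            for belief in np.linspace(0, 1, 11):
                expected = belief * delta_if_bribed + (1 - belief) * delta_if_clean
                assert expected <= 1e-12


def test_params_validation():
    with pytest.raises(ValueError):
        GameParams(F=-1)
    with pytest.raises(ValueError):
        GameParams(A=0)
    with pytest.raises(ValueError):
        GameParams(A=2.5)
    assert DEFAULT_PARAMS == GameParams(10, 0.5, 2, 10, 10)


def test_payoff_vector_role_mapping():
    p = PayoffVector(official=1.0, winner=2.0, loser=3.0)
    assert p.by_firm(1) == (2.0, 3.0)
    assert p.by_firm(2) == (3.0, 2.0)
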