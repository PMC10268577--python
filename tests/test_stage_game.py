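import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enforcegame import (
    CE,
    PopulationState,
    build_strategy_set,
    enforcement_outcome,
    meta_payoffs,
    pd_payoff,
    play_round,
    realize_action,
)
from enforcegame.core_types import active_systems
from enforcegame.reputation import StandingLedger
from enforcegame.stage_game import ATTACK, PEACE


class TestPdPayoff:
    @pytest.mark.parametrize(
        "own,other,expected",
        [("C", "C", 3.0), ("D", "D", 0.0), ("C", "D", -1.0), ("D", "C", 4.0)],
    )
    def test_matrix(self, baseline, own, other, expected):
        assert pd_payoff(own, other, baseline) == expected


class TestRealizeAction:
    def test_no_mistakes_is_identity(self, rng):
        for a in ("C", "D", "A", "B", 0, 1):
            assert all(realize_action(a, 0.0, rng) == a for _ in range(20))

    def test_flip_frequency_tracks_mu(self, baseline, rng):
        n = 200_000
        flips = sum(realize_action("C", baseline.mu, rng) == "D" for _ in range(n))
        sd = np.sqrt(n * baseline.mu * (1 - baseline.mu))
        assert abs(flips - n * baseline.mu) < 3 * sd

    def test_half_mu_is_symmetric(self, rng):
        n = 20_000
        heads = sum(realize_action("C", 0.5, rng) == "C" for _ in range(n))
        assert abs(heads - n / 2) < 4 * np.sqrt(n / 4)


class TestEnforcementOutcome:
    def test_two_cooperators_under_complying_enforcer(self, baseline, rng):
        params = baseline.replace(mu=0.0)
        out = enforcement_outcome([("C", 3.0), ("C", 3.0)], CE, None, params, rng)
        assert out.client_payoffs == (3.5, 3.5)
        assert out.revenue == pytest.approx(3.0)
        assert out.cost == 0.0 and out.punished == (False, False)

    def test_defector_is_taxed_and_punished(self, baseline, rng):
        params = baseline.replace(mu=0.0)
        # defector exploited a cooperator: pre-tax 2+4 vs 2-1
        out = enforcement_outcome([("D", 4.0), ("C", -1.0)], CE, None, params, rng)
        assert out.client_payoffs[0] == pytest.approx(0.7 * 6 - 2)  # 2.2
        assert out.client_payoffs[1] == pytest.approx(0.7 * 1)  # 0.7
        assert out.revenue == pytest.approx(0.3 * 7)  # 2.1
        assert out.cost == pytest.approx(0.1)

    def test_defecting_enforcer_never_punishes(self, baseline, rng, ce2):
        params = baseline.replace(mu=0.0)
        de = next(s for s in ce2 if s.label == "DE")
        out = enforcement_outcome([("D", 0.0), ("D", 0.0)], de, None, params, rng)
        assert out.punished == (False, False) and out.cost == 0.0


class TestMetaPayoffs:
    def test_printed_cells(self, baseline):
        assert meta_payoffs(PEACE, PEACE, 3.0, 2.0, baseline) == (3.0, 2.0)
        assert meta_payoffs(ATTACK, PEACE, 3.0, 2.0, baseline) == pytest.approx((4.4, -4.4))
        assert meta_payoffs(PEACE, ATTACK, 3.0, 2.0, baseline) == pytest.approx((-4.1, 4.1))
        assert meta_payoffs(ATTACK, ATTACK, 3.0, 2.0, baseline) == (-2.0, -3.0)

    @given(
        r_i=st.floats(0, 50), r_j=st.floats(0, 50),
        psi=st.floats(0, 1), loss=st.floats(0, 20),
    )
    @settings(deadline=None, max_examples=300)
    def test_all_cells_match_independent_accounting(self, r_i, r_j, psi, loss):
        """Brute-force oracle: rebuild each cell from transfer/destruction bookkeeping."""
        from enforcegame import baseline_parameters

        params = baseline_parameters(psi=psi, l=max(loss, 0.0))
        for a_i in (ATTACK, PEACE):
            for a_j in (ATTACK, PEACE):
                x_i, x_j = meta_payoffs(a_i, a_j, r_i, r_j, params)
                # oracle: start from revenues, move psi-shares for unilateral
                # attacks, subtract l for every attacked party
                o_i, o_j = r_i, r_j
                if a_i == ATTACK and a_j == PEACE:
                    o_i += psi * r_j
                    o_j -= psi * r_j + params.l
                elif a_j == ATTACK and a_i == PEACE:
                    o_j += psi * r_i
                    o_i -= psi * r_i + params.l
                elif a_i == a_j == ATTACK:
                    o_i -= params.l
                    o_j -= params.l
                assert x_i == pytest.approx(o_i) and x_j == pytest.approx(o_j)
                # l is destroyed, never transferred: total change is -l per attacked
                attacked = (a_j == ATTACK) + (a_i == ATTACK)
                if a_i == ATTACK and a_j == ATTACK:
                    expected_total = r_i + r_j - 2 * params.l
                elif attacked == 1:
                    expected_total = r_i + r_j - params.l
                else:
                    expected_total = r_i + r_j
                assert x_i + x_j == pytest.approx(expected_total)


def _ledger(state, params):
    return StandingLedger(
        (int(i) for i in state.enforcer_ids), active_systems(state.strategy_set), params.kappa
    )


class TestPlayRound:
    def test_two_producers_one_enforcer_worked_example(self, baseline, ce2, rng):
        params = baseline.replace(mu=0.0)
        state = PopulationState.from_counts(ce2, {"CP": 2, "CE": 1})
        ledger = _ledger(state, params)
        record = play_round(state, ledger, params, rng)
        producer_pay = [record.payoffs[int(i)] for i in state.producer_ids]
        enforcer = int(state.enforcer_ids[0])
        assert producer_pay == pytest.approx([3.5, 3.5])
        assert record.payoffs[enforcer] == pytest.approx(3.0 - 0.3)  # R - f, unmatched in meta

    def test_revenue_conservation_every_round(self, baseline, rng):
        sset = build_strategy_set("CE16")
        for _ in range(25):
            state = PopulationState.random(sset, 40, rng)
            ledger = _ledger(state, baseline)
            record = play_round(state, ledger, baseline, rng)
            taxed = 0.0
            for (i, j), e in zip(record.producer_pairs, record.pair_enforcers):
                if e < 0:
                    continue
                a_i, a_j = record.actions[i], record.actions[j]
                taxed += baseline.tau * (
                    2 * baseline.w
                    + pd_payoff(a_i, a_j, baseline)
                    + pd_payoff(a_j, a_i, baseline)
                )
            assert sum(record.revenues.values()) == pytest.approx(taxed)

    def test_all_cooperative_state_is_peaceful_and_scores_stay_zero(self, baseline, ce2, rng):
        params = baseline.replace(mu=0.0)
        state = PopulationState.from_counts(ce2, {"CP": 30, "CE": 10})
        ledger = _ledger(state, params)
        for _ in range(20):
            record = play_round(state, ledger, params, rng)
            assert all(not any(p for _, p in c.clients) for c in record.conducts.values())
            assert all(
                c.meta is None or not c.meta.attacked for c in record.conducts.values()
            )
        assert all(z == 0 for z in ledger.scores.values())

    def test_mutual_defection_among_defecting_enforcers(self, baseline, ce2, rng):
        params = baseline.replace(mu=0.0)
        state = PopulationState.from_counts(ce2, {"DP": 8, "DE": 2})
        ledger = _ledger(state, params)
        record = play_round(state, ledger, params, rng)
        # both DE attack from round one, so each walks away with R - l
        for e in (int(x) for x in state.enforcer_ids):
            assert record.payoffs[e] == pytest.approx(record.revenues[e] - params.l)
        # attacking a good-standing coplayer violates the CE standard
        assert all(ledger.standing(int(e), "CE") == "bad" for e in state.enforcer_ids)

    def test_degenerate_rounds_do_not_crash(self, baseline, ce2, rng):
        params = baseline.replace(mu=0.0)
        # no enforcers: untaxed production
        state = PopulationState.from_counts(ce2, {"CP": 4})
        record = play_round(state, _ledger(state, params), params, rng)
        assert all(record.payoffs[int(i)] == pytest.approx(5.0) for i in state.producer_ids)
        # single producer: untaxed autarky
        state = PopulationState.from_counts(ce2, {"CP": 1, "CE": 2})
        record = play_round(state, _ledger(state, params), params, rng)
        lone = int(state.producer_ids[0])
        assert record.payoffs[lone] == pytest.approx(params.w)
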