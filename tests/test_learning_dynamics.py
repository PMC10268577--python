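import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enforcegame import (
    CE,
    CP,
    DE,
    DP,
    PopulationState,
    build_strategy_set,
    draw_revision_class,
    hypothetical_payoff,
    logit_choice,
    logit_probabilities,
    revise_agent,
    run_exact_best_reply,
    run_markov_chain,
)
from enforcegame.learning_dynamics import _hypothetical_from_counts


class TestLogitChoice:
    def test_equal_payoffs_split_evenly(self):
        assert logit_probabilities([1.0, 1.0], eta=0.7) == pytest.approx([0.5, 0.5])

    def test_unit_gap_at_unit_imprecision(self):
        probs = logit_probabilities([1.0, 0.0], eta=1.0)
        assert probs[0] == pytest.approx(math.e / (1 + math.e))  # ~0.7311

    def test_zero_imprecision_is_exact_best_response(self, rng):
        assert logit_choice({"X": 1.0, "Y": 0.0}, eta=0.0, rng=rng) == "X"
        probs = logit_probabilities([2.0, 2.0, 1.0], eta=0.0)
        assert probs == pytest.approx([0.5, 0.5, 0.0])

    def test_huge_payoffs_do_not_overflow(self):
        probs = logit_probabilities([1e6, 1e6 - 1], eta=0.01)
        assert np.isfinite(probs).all() and probs.sum() == pytest.approx(1.0)

    @given(
        payoffs=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        eta=st.floats(0.0, 10.0),
        shift=st.floats(-100, 100),
    )
    @settings(deadline=None, max_examples=200)
    def test_normalization_monotonicity_translation_invariance(self, payoffs, eta, shift):
        probs = logit_probabilities(payoffs, eta)
        assert probs.sum() == pytest.approx(1.0)
        order = np.argsort(payoffs)
        assert all(np.diff(probs[order]) >= -1e-12)  # monotone in payoffs
        if eta > 1e-6:  # at eta = 0 a shift can create or break exact-max ties
            shifted = logit_probabilities([x + shift for x in payoffs], eta)
            assert shifted == pytest.approx(probs, abs=1e-6)

    def test_empty_menu_rejected(self, rng):
        with pytest.raises(ValueError):
            logit_choice({}, eta=1.0, rng=rng)


class TestRevisionClasses:
    def test_degenerate_gammas(self, baseline, ce2, rng):
        state = PopulationState.from_counts(ce2, {"CP": 3, "CE": 2})
        with pytest.warns(UserWarning):
            producers_only = baseline.replace(gamma=(0.0, 0.0, 1.0))
            full_only = baseline.replace(gamma=(1.0, 0.0, 0.0))
        for _ in range(20):
            draw = draw_revision_class(state, producers_only.gamma, rng)
            assert draw.revision_class == "producer"
            assert all(ce2[m].is_producer for m in draw.menu)
            draw = draw_revision_class(state, full_only.gamma, rng)
            assert draw.revision_class == "population"
            assert len(draw.menu) == len(ce2)

    def test_class_frequencies_match_gamma(self, baseline, ce2, rng):
        state = PopulationState.from_counts(ce2, {"CP": 3, "CE": 2})
        n = 20_000
        seen = {"producer": 0, "enforcer": 0, "population": 0}
        for _ in range(n):
            seen[draw_revision_class(state, baseline.gamma, rng).revision_class] += 1
        for cls, g in [("population", 0.1), ("enforcer", 0.3), ("producer", 0.6)]:
            sd = math.sqrt(n * g * (1 - g))
            assert abs(seen[cls] - n * g) < 4 * sd

    def test_empty_class_falls_back_to_population(self, baseline, ce2, rng):
        state = PopulationState.from_counts(ce2, {"CP": 5})  # no enforcers
        with pytest.warns(UserWarning):
            enforcers_only = baseline.replace(gamma=(0.0, 1.0, 0.0))
        draw = draw_revision_class(state, enforcers_only.gamma, rng)
        assert draw.revision_class == "population"


class TestReviseAgent:
    def test_pure_mistakes_are_uniform(self, baseline, ce2, rng):
        params = baseline.replace(epsilon=1.0)
        state = PopulationState.from_counts(ce2, {"CP": 5, "CE": 3})
        menu = tuple(range(len(ce2)))
        picks = np.zeros(len(ce2))
        n = 8000
        for _ in range(n):
            new = revise_agent(state, None, params, menu, agent=0, rng=rng)
            picks[new.assignment[0]] += 1
        assert picks.min() > n / len(ce2) - 4 * math.sqrt(n * 0.25)

    def test_exact_best_response_picks_higher_realized_payoff(self, baseline, ce2, rng):
        from enforcegame.period_simulator import PeriodResult

        params = baseline.replace(epsilon=0.0, eta=0.0)
        state = PopulationState.from_counts(ce2, {"CP": 4, "DP": 1, "CE": 2})
        fake = PeriodResult(
            T=1,
            agent_averages=np.zeros(state.N),
            strategy_averages={"CP": 3.5, "DP": 2.2, "CE": 2.7, "DE": None},
            counts=state.counts_by_label(),
        )
        dp_agent = int(state.producer_ids[-1])
        menu = tuple(k for k, s in enumerate(ce2) if s.is_producer)
        new = revise_agent(state, fake, params, menu, dp_agent, rng)
        assert ce2[new.assignment[dp_agent]] == CP

    def test_infinite_imprecision_is_uniform(self, baseline, ce2, rng):
        params = baseline.replace(epsilon=0.0, eta=1e9)
        state = PopulationState.from_counts(ce2, {"CP": 4, "DP": 4, "CE": 2})
        menu = (0, 1)
        picks = {0: 0, 1: 0}
        n = 4000
        for _ in range(n):
            new = revise_agent(state, None, params, menu, agent=0, rng=rng)
            picks[int(new.assignment[0])] += 1
        assert abs(picks[0] - n / 2) < 4 * math.sqrt(n / 4)


class TestHypotheticalPayoff:
    def test_cooperative_state_closed_forms(self, exact_regime, ce2):
        state = PopulationState.from_counts(ce2, {"CP": 36, "CE": 14})
        assert hypothetical_payoff(CP, state, exact_regime) == pytest.approx(3.5)
        # a CE against 36 producers: tau*(w+b-c)*n_P/n_E - f
        assert hypothetical_payoff(CE, state, exact_regime) == pytest.approx(
            0.3 * 5 * 36 / 14 - 0.3
        )

    def test_deviant_defector_payoff(self, exact_regime, ce2):
        state = PopulationState.from_counts(ce2, {"CP": 35, "DP": 1, "CE": 14})
        assert hypothetical_payoff(DP, state, exact_regime) == pytest.approx(0.7 * 6 - 2)

    def test_defection_state_closed_forms(self, exact_regime, ce2):
        state = PopulationState.from_counts(ce2, {"DP": 46, "DE": 4})
        assert hypothetical_payoff(DE, state, exact_regime) == pytest.approx(
            0.3 * 2 * 46 / 4 - 5
        )
        assert hypothetical_payoff(DP, state, exact_regime) == pytest.approx(1.4)

    def test_lone_complier_among_defecting_enforcers_fights_and_pays_f(
        self, exact_regime, ce2
    ):
        # a CE candidate in a DE world attacks (they are all bad) and is attacked
        state = PopulationState.from_counts(ce2, {"DP": 45, "CE": 1, "DE": 4})
        expected_de = 0.3 * 2 * 45 / 5 - 5
        assert hypothetical_payoff(CE, state, exact_regime) == pytest.approx(
            expected_de - 0.3
        )

    def test_engine_parity_on_random_compositions(self, baseline):
        """The compiled analytic payoff agrees with the reference to 1e-12."""
        from enforcegame._engine import hypothetical_payoff_fast

        rng = np.random.default_rng(17)
        for preset in ("CE2", "CE16", "PE2", "PE16", "CEPE3"):
            sset = build_strategy_set(preset)
            for _ in range(40):
                counts = rng.multinomial(50, np.ones(len(sset)) / len(sset))
                for k in range(len(sset)):
                    if counts[k] == 0:
                        continue
                    ref = _hypothetical_from_counts(k, counts, sset, baseline)
                    fast = hypothetical_payoff_fast(k, counts, sset, baseline)
                    assert fast == pytest.approx(ref, abs=1e-12)


class TestExactBestReply:
    def test_absorbing_states_stay_put(self, exact_regime, ce2, rng):
        coop = PopulationState.from_counts(ce2, {"CP": 36, "CE": 14})
        res = run_exact_best_reply(coop, exact_regime, rng)
        assert res.absorbed == "E_C" and res.revisions == 0
        conflict = PopulationState.from_counts(ce2, {"DP": 46, "DE": 4})
        res = run_exact_best_reply(conflict, exact_regime, rng)
        assert res.absorbed == "E_D" and res.revisions == 0

    def test_single_enforcer_population_defects(self, exact_regime, ce2, rng):
        state = PopulationState.from_counts(ce2, {"CP": 48, "DP": 1, "CE": 1})
        assert run_exact_best_reply(state, exact_regime, rng).absorbed == "E_D"

    def test_warns_outside_analytical_regime(self, baseline, ce2, rng):
        state = PopulationState.from_counts(ce2, {"CP": 36, "CE": 14})
        with pytest.warns(UserWarning, match="analytical regime"):
            run_exact_best_reply(state, baseline, rng, max_sweeps=1)


class TestMarkovChain:
    def test_one_period_time_average_is_initial_share(self, baseline, ce2, rng):
        state = PopulationState.from_counts(ce2, {"CP": 30, "DP": 6, "CE": 10, "DE": 4})
        res = run_markov_chain(baseline, ce2, state, periods=1, rng=rng, engine="reference")
        assert res.share_avg == pytest.approx(np.array([30, 6, 10, 4]) / 50)

    def test_shares_sum_to_one_every_record(self, baseline, ce2, rng):
        state = PopulationState.random(ce2, 50, rng)
        res = run_markov_chain(
            baseline, ce2, state, periods=300, rng=rng, engine="fast", record_every=10
        )
        assert (res.counts.sum(axis=1) == 50).all()
        assert res.share_avg.sum() == pytest.approx(1.0)

    def test_ergodicity_every_strategy_appears(self, baseline, ce2, rng):
        """With epsilon > 0 every strategy in the active set is adopted eventually."""
        state = PopulationState.from_counts(ce2, {"CP": 50})
        res = run_markov_chain(
            baseline, ce2, state, periods=4000, rng=rng, engine="fast", record_every=1
        )
        assert (res.counts.max(axis=0) > 0).all()

    def test_engines_agree_statistically(self, baseline, ce2):
        """Reference and compiled paths sample the same chain law."""
        init = PopulationState.from_counts(ce2, {"CP": 36, "CE": 14})
        ref = run_markov_chain(
            baseline, ce2, init, 1200, rng=np.random.default_rng(5), engine="reference"
        )
        fast = run_markov_chain(
            baseline, ce2, init, 1200, rng=np.random.default_rng(6), engine="fast"
        )
        assert np.abs(ref.share_avg - fast.share_avg).max() < 0.12

    def test_identical_seeds_reproduce_exactly(self, baseline, ce2):
        init = PopulationState.random(ce2, 50, np.random.default_rng(0))
        a = run_markov_chain(baseline, ce2, init, 500, rng=np.random.default_rng(7), engine="fast")
        b = run_markov_chain(baseline, ce2, init, 500, rng=np.random.default_rng(7), engine="fast")
        assert (a.counts == b.counts).all()
        assert a.share_avg == pytest.approx(b.share_avg, abs=0)
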