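"""Between-period strategy revision and long-run distribution estimation.

After each period exactly one agent revises.  A revision class is drawn
first: with probability ``gamma_p`` a producer revises among producer
strategies, with ``gamma_e`` an enforcer revises among enforcer
strategies, and with ``gamma_pe`` an agent drawn from the whole
population chooses over the full strategy set.  With probability
``epsilon`` the revising agent adopts a uniformly random strategy from
her menu (a revision mistake / mutation); otherwise she plays a logit
best response with imprecision ``eta`` to the realized per-strategy
average payoffs of the period just played.  Strategies with no current
users have no realized payoff; they are scored by an analytic
expectation (:func:`hypothetical_payoff`) computed in the limiting
regime of the model's closed-form analysis.

The module also implements the structured exact best-reply dynamic used
for the basin-of-attraction results, and the invariant-distribution
estimator (time averages over long runs from random initial
conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analytics import alpha_cooperation, alpha_defection
from .core_types import (
    CE_SYSTEM,
    COOPERATE,
    PE_SYSTEM,
    ModelParameters,
    PopulationState,
    StrategyCode,
)
from .period_simulator import PeriodResult, play_period

E_C = "E_C"
E_D = "E_D"
UNRESOLVED = "none"


# ---------------------------------------------------------------------------
# logit choice
# ---------------------------------------------------------------------------

def logit_probabilities(payoffs: Sequence[float], eta: float) -> np.ndarray:
    """Choice probabilities ``exp(pi_X/eta) / sum_Y exp(pi_Y/eta)``.

    ``eta = 0`` degenerates to the exact best response: probability is split
    uniformly over the maximizers.  Computed with max-subtraction so large
    payoffs cannot overflow.
    """
    pi = np.asarray(payoffs, dtype=float)
    if pi.size == 0:
        raise ValueError("empty strategy menu")
    if eta < 0:
        raise ValueError(f"eta must be non-negative, got {eta}")
    if eta == 0:
        best = pi == pi.max()
        return best / best.sum()
    z = np.exp((pi - pi.max()) / eta)
    return z / z.sum()


def logit_choice(payoffs, eta: float, rng: np.random.Generator):
    """Sample one strategy from a payoff menu via the logit rule.

    ``payoffs`` may be a mapping (a key is returned) or a sequence (an index
    is returned).
    """
    if isinstance(payoffs, dict):
        keys = list(payoffs)
        probs = logit_probabilities([payoffs[k] for k in keys], eta)
        return keys[rng.choice(len(keys), p=probs)]
    probs = logit_probabilities(payoffs, eta)
    return int(rng.choice(len(probs), p=probs))


# ---------------------------------------------------------------------------
# revision protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RevisionDraw:
    """A drawn revision opportunity: who revises and over which menu."""

    revision_class: str  # "producer" | "enforcer" | "population"
    agent: int
    menu: tuple[int, ...]  # indices into the strategy set


def _menus(strategy_set: Sequence[StrategyCode]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    producers = tuple(k for k, s in enumerate(strategy_set) if s.is_producer)
    enforcers = tuple(k for k, s in enumerate(strategy_set) if s.is_enforcer)
    return producers, enforcers


def draw_revision_class(
    state: PopulationState, gamma: tuple[float, float, float], rng: np.random.Generator
) -> RevisionDraw:
    """Draw the revision class, the revising agent, and her menu.

    ``gamma`` is ``(gamma_pe, gamma_e, gamma_p)``.  If the drawn class is
    empty (no producers or no enforcers currently exist), the draw falls
    back to the whole-population class so the chain never stalls.
    """
    g_pe, g_e, g_p = gamma
    u = rng.random()
    prod_menu, enf_menu = _menus(state.strategy_set)
    producers, enforcers = state.producer_ids, state.enforcer_ids
    if u < g_p and len(producers) > 0:
        agent = int(producers[rng.integers(len(producers))])
        return RevisionDraw("producer", agent, prod_menu)
    if g_p <= u < g_p + g_e and len(enforcers) > 0:
        agent = int(enforcers[rng.integers(len(enforcers))])
        return RevisionDraw("enforcer", agent, enf_menu)
    agent = int(rng.integers(state.N))
    return RevisionDraw("population", agent, prod_menu + enf_menu)


# ---------------------------------------------------------------------------
# analytic expected payoffs (the limiting regime of the closed-form analysis)
# ---------------------------------------------------------------------------

def _system_index(s: StrategyCode) -> int:
    if s.system == CE_SYSTEM:
        return 0
    if s.system == PE_SYSTEM:
        return 1
    return -1


def _long_run_bad(
    strategy_set: Sequence[StrategyCode], counts: np.ndarray
) -> np.ndarray:
    """Long-run standing of each present strategy under the CE and PE standards.

    In the no-mistake, infinite-punishment limit a strategy that violates a
    standard with positive per-round probability ends up in permanent bad
    standing under that standard.  Violation opportunities depend on which
    other strategies are present and on *their* standings, so the set of
    bad-standing strategies is grown monotonically to its least fixed point,
    starting from the all-good period-start configuration.
    """
    S = len(strategy_set)
    bad = np.zeros((S, 2), dtype=bool)  # columns: CE, PE
    n_P = sum(int(counts[k]) for k, s in enumerate(strategy_set) if s.is_producer)
    n_CP = sum(
        int(counts[k])
        for k, s in enumerate(strategy_set)
        if s.is_producer and s.producer_action == COOPERATE
    )
    n_DP = n_P - n_CP
    n_E = sum(int(counts[k]) for k, s in enumerate(strategy_set) if s.is_enforcer)
    changed = True
    while changed:
        changed = False
        for x, sx in enumerate(strategy_set):
            if not sx.is_enforcer or counts[x] == 0:
                continue
            a_coop, a_def, a_good, a_bad = sx.bits
            vce = False
            vpe = False
            if n_P >= 2:
                if n_CP > 0 and a_coop == 1:
                    vce = True
                if n_DP > 0 and a_def == 0:
                    vce = True
            if n_E >= 2:
                sysx = _system_index(sx)
                for y, sy in enumerate(strategy_set):
                    if not sy.is_enforcer:
                        continue
                    avail = counts[y] - (1 if y == x else 0)
                    if avail <= 0:
                        continue
                    coplayer_bad = bad[y, sysx] if sysx >= 0 else False
                    att = a_bad if coplayer_bad else a_good
                    if bool(att) != bool(bad[y, 0]):
                        vce = True
                    if bool(att) != bool(bad[y, 1]):
                        vpe = True
            if vce and not bad[x, 0]:
                bad[x, 0] = True
                changed = True
            if vpe and not bad[x, 1]:
                bad[x, 1] = True
                changed = True
    return bad


def _hypothetical_from_counts(
    s_idx: int,
    counts: np.ndarray,
    strategy_set: Sequence[StrategyCode],
    params: ModelParameters,
) -> float:
    """Expected per-round payoff of strategy ``s_idx`` against composition ``counts``.

    Computed in the ``mu = 0``, ``delta -> 1``, ``kappa -> infinity`` regime:
    matchings are averaged out and every enforcer sits at its long-run
    standing.  ``counts`` must already include the candidate in her slot.
    """
    s = strategy_set[s_idx]
    n_P = sum(int(counts[k]) for k, st in enumerate(strategy_set) if st.is_producer)
    n_CP = sum(
        int(counts[k])
        for k, st in enumerate(strategy_set)
        if st.is_producer and st.producer_action == COOPERATE
    )
    n_DP = n_P - n_CP
    n_E = sum(int(counts[k]) for k, st in enumerate(strategy_set) if st.is_enforcer)

    if s.is_producer:
        if n_P < 2:
            return params.w  # always unmatched: untaxed autarky
        coop = 1 if s.producer_action == COOPERATE else 0
        partner_coop = (n_CP - coop) / (n_P - 1)
        pd = params.b * partner_coop - params.c * coop
        punish_prob = 0.0
        if n_E > 0:
            total = 0.0
            for k, st in enumerate(strategy_set):
                if st.is_enforcer:
                    bit = st.bits[0] if coop else st.bits[1]
                    total += counts[k] * bit
            punish_prob = total / n_E
        return (1 - params.tau) * (params.w + pd) - params.p * punish_prob

    # enforcer candidate
    bad = _long_run_bad(strategy_set, counts)
    if n_P >= 2 and n_E > 0:
        R = params.tau * (n_P * params.w + (params.b - params.c) * n_CP) / n_E
        v_cost = params.v * (s.bits[0] * n_CP + s.bits[1] * n_DP) / n_E
    else:
        R = 0.0
        v_cost = 0.0
    meta = 0.0
    if n_E >= 2:
        sysx = _system_index(s)
        for y, sy in enumerate(strategy_set):
            if not sy.is_enforcer:
                continue
            avail = counts[y] - (1 if y == s_idx else 0)
            if avail <= 0:
                continue
            q = avail / (n_E - 1)
            coplayer_bad = bad[y, sysx] if sysx >= 0 else False
            att_i = s.bits[3] if coplayer_bad else s.bits[2]
            sysy = _system_index(sy)
            my_bad = bad[s_idx, sysy] if sysy >= 0 else False
            att_j = sy.bits[3] if my_bad else sy.bits[2]
            if att_i and att_j:
                adj = -params.l
            elif att_i:
                adj = params.psi * R
            elif att_j:
                adj = -params.psi * R - params.l
            else:
                adj = 0.0
            meta += q * adj
    return R + meta - v_cost - (params.f if s.informed else 0.0)


def hypothetical_payoff(
    strategy: StrategyCode | int, state: PopulationState, params: ModelParameters
) -> float:
    """Analytic expected per-round payoff of a candidate strategy.

    ``state`` must describe the population with the candidate already
    occupying the revising agent's slot.  ``strategy`` may be given as a
    code (must belong to the state's strategy set) or an index.
    """
    if isinstance(strategy, StrategyCode):
        s_idx = state.strategy_set.index(strategy)
    else:
        s_idx = int(strategy)
    return _hypothetical_from_counts(s_idx, state.counts, state.strategy_set, params)


def _menu_payoffs(
    state: PopulationState,
    period_result: Optional[PeriodResult],
    params: ModelParameters,
    menu: Sequence[int],
    agent: int,
) -> list[float]:
    counts = state.counts
    cur = int(state.assignment[agent])
    payoffs = []
    for m in menu:
        label = state.strategy_set[m].label
        realized = period_result.strategy_averages.get(label) if period_result else None
        if realized is not None:
            payoffs.append(realized)
        else:
            adjusted = counts.copy()
            adjusted[cur] -= 1
            adjusted[m] += 1
            payoffs.append(_hypothetical_from_counts(m, adjusted, state.strategy_set, params))
    return payoffs


def revise_agent(
    state: PopulationState,
    period_result: Optional[PeriodResult],
    params: ModelParameters,
    menu: Sequence[int],
    agent: int,
    rng: np.random.Generator,
) -> PopulationState:
    """One revision: mistake with probability ``epsilon``, else logit choice.

    The logit input is the realized per-strategy average payoff from the last
    period, with :func:`hypothetical_payoff` filling in strategies that had
    no users.
    """
    if len(menu) == 0:
        raise ValueError("empty revision menu")
    if rng.random() < params.epsilon:
        choice = menu[rng.integers(len(menu))]
    else:
        payoffs = _menu_payoffs(state, period_result, params, menu, agent)
        choice = menu[logit_choice(payoffs, params.eta, rng)]
    return state.with_strategy(agent, int(choice))


# ---------------------------------------------------------------------------
# chain runners
# ---------------------------------------------------------------------------

@dataclass
class ChainResult:
    """One simulated chain: recorded counts and time-average shares of N."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (n_records, n_strategies)
    record_every: int
    share_avg: np.ndarray  # (n_strategies,), averaged over all periods
    final_assignment: np.ndarray
    periods: int

    def to_frame(self) -> pd.DataFrame:
        period = np.arange(self.counts.shape[0]) * self.record_every
        frame = pd.DataFrame(self.counts, columns=list(self.labels))
        frame.insert(0, "period", period)
        return frame.melt(id_vars="period", var_name="strategy", value_name="count")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def run_markov_chain(
    params: ModelParameters,
    strategy_set: Sequence[StrategyCode],
    initial_state: PopulationState,
    periods: int,
    rng=None,
    engine: str = "fast",
    record_every: int = 1,
) -> ChainResult:
    """Alternate one period of play and one revision, for ``periods`` periods.

    Strategy counts are recorded for the state that played each period and
    time averages run over *all* periods (no burn-in).  ``engine="fast"``
    uses the compiled kernel; ``engine="reference"`` runs the readable
    pure-Python implementation (identical model, different random streams).
    """
    if periods < 1:
        raise ValueError("periods must be >= 1")
    rng = _as_rng(rng)
    labels = tuple(s.label for s in strategy_set)
    if engine == "fast":
        from . import _engine

        seed = int(rng.integers(2**31 - 1))
        counts, share_avg, final_assignment = _engine.run_chain(
            np.asarray(initial_state.assignment, dtype=np.int64),
            strategy_set,
            params,
            periods,
            seed,
            record_every,
        )
        return ChainResult(labels, counts, record_every, share_avg, final_assignment, periods)
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")

    state = initial_state.copy()
    S = len(strategy_set)
    n_records = (periods + record_every - 1) // record_every
    recorded = np.zeros((n_records, S), dtype=np.int64)
    share_sum = np.zeros(S)
    rec_i = 0
    for t in range(periods):
        counts = state.counts
        share_sum += counts / state.N
        if t % record_every == 0:
            recorded[rec_i] = counts
            rec_i += 1
        result = play_period(state, params, rng)
        draw = draw_revision_class(state, params.gamma, rng)
        state = revise_agent(state, result, params, draw.menu, draw.agent, rng)
    return ChainResult(
        labels,
        recorded[:rec_i],
        record_every,
        share_sum / periods,
        state.assignment.copy(),
        periods,
    )


@dataclass
class RunSummary:
    """Cross-run summary of time-average strategy shares.

    Shares are fractions of the whole population ``N`` (producer and enforcer
    strategies jointly sum to one).  The standard error is the sample
    standard deviation across runs divided by ``sqrt(runs)``.
    """

    labels: tuple[str, ...]
    mean_shares: np.ndarray
    se: np.ndarray
    per_run_shares: np.ndarray  # (runs, n_strategies)
    runs: int
    periods: int
    seeds: tuple[int, ...]

    def share(self, label: str) -> float:
        return float(self.mean_shares[self.labels.index(label)])

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    @property
    def max_se(self) -> float:
        return float(self.se.max())

    def to_frame(self, strategy_set: Optional[Sequence[StrategyCode]] = None) -> pd.DataFrame:
        systems = [""] * len(self.labels)
        if strategy_set is not None:
            systems = [(s.system or "") for s in strategy_set]
        return pd.DataFrame(
            {
                "strategy": list(self.labels),
                "system": systems,
                "mean_share": self.mean_shares,
                "se": self.se,
                "runs": self.runs,
                "periods": self.periods,
            }
        )


def run_invariant_estimate(
    params: ModelParameters,
    strategy_set: Sequence[StrategyCode],
    periods: int,
    runs: int,
    seed: int,
    engine: str = "fast",
    record_every: int = 0,
) -> RunSummary:
    """Estimate the invariant distribution by time averages over independent runs.

    Each run starts from an independently drawn random initial condition
    (every agent's strategy i.i.d. uniform over the active set) and iterates
    ``periods`` period/revision steps; the estimate is the cross-run mean of
    the per-run time-average shares.
    """
    if runs < 2:
        raise ValueError("need at least two runs to form a standard error")
    children = np.random.SeedSequence(seed).spawn(runs)
    per_run = np.zeros((runs, len(strategy_set)))
    run_seeds = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        run_seeds.append(int(child.generate_state(1)[0] % (2**31 - 1)))
        init = PopulationState.random(strategy_set, params.N, rng)
        rec = record_every if record_every > 0 else periods  # keep memory flat
        result = run_markov_chain(
            params, strategy_set, init, periods, rng=rng, engine=engine, record_every=rec
        )
        per_run[r] = result.share_avg
    mean = per_run.mean(axis=0)
    se = per_run.std(axis=0, ddof=1) / np.sqrt(runs)
    return RunSummary(
        labels=tuple(s.label for s in strategy_set),
        mean_shares=mean,
        se=se,
        per_run_shares=per_run,
        runs=runs,
        periods=periods,
        seeds=tuple(run_seeds),
    )


# ---------------------------------------------------------------------------
# exact best-reply learning
# ---------------------------------------------------------------------------

@dataclass
class BestReplyResult:
    """Outcome of the structured exact best-reply dynamic."""

    absorbed: str  # "E_C" | "E_D" | "none"
    sweeps: int
    revisions: int
    final_state: PopulationState
    trajectory: list[dict[str, int]]


def _bracket_ints(alpha: float, n: int) -> set[int]:
    lo, hi = alpha * n - 1, alpha * n
    return {k for k in range(n + 1) if lo <= k <= hi}


def _absorbed_label(state: PopulationState, params: ModelParameters) -> Optional[str]:
    counts = state.counts_by_label()
    n = state.N
    n_ce, n_de = counts.get("CE", 0), counts.get("DE", 0)
    n_cp, n_dp = counts.get("CP", 0), counts.get("DP", 0)
    pure_c = n_cp + n_ce == n and n_ce == state.n_E
    pure_d = n_dp + n_de == n and n_de == state.n_E
    if pure_c and n_ce in _bracket_ints(alpha_cooperation(params), n):
        return E_C
    if pure_d and n_de in _bracket_ints(alpha_defection(params), n):
        return E_D
    return None


def run_exact_best_reply(
    initial_state: PopulationState,
    params: ModelParameters,
    rng=None,
    max_sweeps: int = 500,
) -> BestReplyResult:
    """Run the structured exact best-reply dynamic until absorption.

    The revision order follows the analytical protocol: all producers one by
    one (without replacement), then one enforcer; repeated until every
    enforcer has revised; then all producers once more; then a single
    whole-population draw with the full menu; then the cycle restarts.  Each
    revision adopts the strategy maximizing the analytic expected per-round
    payoff (ties broken uniformly).  The run stops as soon as the state
    enters the cooperation or defection absorbing bracket.

    Intended for the analytical regime (``mu = v = eta = epsilon = 0``);
    a warning is emitted when called outside it.
    """
    if any(x != 0 for x in (params.mu, params.v, params.eta, params.epsilon)):
        warnings.warn(
            "exact best-reply dynamic called outside the analytical regime "
            "(mu = v = eta = epsilon = 0); basin results need not apply",
            stacklevel=2,
        )
    rng = _as_rng(rng)
    sset = initial_state.strategy_set
    S = len(sset)
    N = initial_state.N
    assignment = initial_state.assignment.copy()
    counts = np.bincount(assignment, minlength=S)
    is_prod = np.array([s.is_producer for s in sset])
    prod_menu, enf_menu = _menus(sset)
    full_menu = prod_menu + enf_menu
    by_label = {s.label: k for k, s in enumerate(sset)}
    i_cp, i_dp = by_label.get("CP", -1), by_label.get("DP", -1)
    i_ce, i_de = by_label.get("CE", -1), by_label.get("DE", -1)
    e_c_ints = _bracket_ints(alpha_cooperation(params), N)
    e_d_ints = _bracket_ints(alpha_defection(params), N)
    enf_cols = np.flatnonzero(~is_prod)

    def absorbed() -> Optional[str]:
        n_e = int(counts[enf_cols].sum())
        if (
            i_cp >= 0 and i_ce >= 0
            and counts[i_cp] + counts[i_ce] == N
            and counts[i_ce] == n_e and n_e in e_c_ints
        ):
            return E_C
        if (
            i_dp >= 0 and i_de >= 0
            and counts[i_dp] + counts[i_de] == N
            and counts[i_de] == n_e and n_e in e_d_ints
        ):
            return E_D
        return None

    cache: dict = {}
    revisions = 0

    def best_reply(agent: int, menu: tuple[int, ...]) -> Optional[str]:
        # candidate payoffs depend only on (composition, current strategy,
        # menu), so they are memoized across agents within the run
        nonlocal revisions
        revisions += 1
        cur = int(assignment[agent])
        key = (counts.tobytes(), cur, menu)
        payoffs = cache.get(key)
        if payoffs is None:
            payoffs = np.empty(len(menu))
            for k, m in enumerate(menu):
                counts[cur] -= 1
                counts[m] += 1
                payoffs[k] = _hypothetical_from_counts(m, counts, sset, params)
                counts[m] -= 1
                counts[cur] += 1
            cache[key] = payoffs
        best = np.flatnonzero(payoffs >= payoffs.max() - 1e-9)
        choice = menu[int(best[0] if len(best) == 1 else best[rng.integers(len(best))])]
        if choice != cur:
            assignment[agent] = choice
            counts[cur] -= 1
            counts[choice] += 1
        return absorbed()

    def result(label: str, sweeps: int) -> BestReplyResult:
        final = PopulationState(sset, assignment)
        trajectory.append(final.counts_by_label())
        return BestReplyResult(label, sweeps, revisions, final, trajectory)

    trajectory: list[dict[str, int]] = [initial_state.counts_by_label()]
    label = absorbed()
    if label is not None:
        return result(label, 0)

    for sweep in range(1, max_sweeps + 1):
        prod_ids = np.flatnonzero(is_prod[assignment])
        enf_ids = np.flatnonzero(~is_prod[assignment])
        enforcer_order = list(rng.permutation(enf_ids)) if len(enf_ids) else [None]
        for e in enforcer_order:
            for a in rng.permutation(prod_ids):
                label = best_reply(int(a), prod_menu)
                if label is not None:
                    return result(label, sweep)
            if e is not None:
                label = best_reply(int(e), enf_menu)
                if label is not None:
                    return result(label, sweep)
        if len(enf_ids):
            for a in rng.permutation(prod_ids):
                label = best_reply(int(a), prod_menu)
                if label is not None:
                    return result(label, sweep)
        label = best_reply(int(rng.integers(N)), full_menu)
        if label is not None:
            return result(label, sweep)
    return result(UNRESOLVED, max_sweeps)
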