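"""One round of the three-step stage game.

Step 1 (production): producers pair uniformly at random and play a
prisoner's dilemma on top of their autarky payoff ``w``.  Step 2
(enforcement): each producer pair is assigned to a uniformly random
enforcer, who taxes both clients at rate ``tau`` and may punish either
one.  Step 3 (meta-enforcement): enforcers pair uniformly at random and
each chooses to attack or stay peaceful over the revenue collected in
step 2.  Every binary choice is executed with an action-mistake
probability ``mu``.  Scores under every active reputation system are
updated at the end of the round from realized conduct.

Conventions for odd headcounts: an unmatched producer consumes her
autarky payoff ``w`` untaxed and faces no enforcement; an unmatched
enforcer skips the meta step and keeps her revenue; missing steps are
judged vacuously compliant.  With no enforcers present, production
still happens but nobody is taxed or punished.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_types import (
    COOPERATE,
    DEFECT,
    ModelParameters,
    PopulationState,
    StrategyCode,
)
from .reputation import (
    BAD,
    COMPLIANCE_BY_SYSTEM,
    MetaConduct,
    RoundConduct,
    StandingLedger,
)

ATTACK = "A"
PEACE = "B"

_FLIP = {COOPERATE: DEFECT, DEFECT: COOPERATE, ATTACK: PEACE, PEACE: ATTACK, 0: 1, 1: 0}


def pd_payoff(own: str, other: str, params: ModelParameters) -> float:
    """Pre-tax production payoff from the PD, excluding the autarky payoff."""
    gain = params.b if other == COOPERATE else 0.0
    cost = params.c if own == COOPERATE else 0.0
    return gain - cost


def realize_action(prescribed, mu: float, rng: np.random.Generator):
    """Execute a binary action: as prescribed w.p. ``1 - mu``, flipped w.p. ``mu``."""
    if mu > 0 and rng.random() < mu:
        return _FLIP[prescribed]
    return prescribed


@dataclass(frozen=True)
class EnforcementOutcome:
    client_payoffs: tuple[float, ...]
    punished: tuple[bool, ...]
    revenue: float
    cost: float


def enforcement_outcome(
    client_results: Sequence[tuple[str, float]],
    strategy: StrategyCode,
    standings,  # unused: punish decisions condition only on client actions
    params: ModelParameters,
    rng: np.random.Generator,
) -> EnforcementOutcome:
    """Tax and possibly punish one pair of clients.

    ``client_results`` holds ``(realized PD action, PD payoff)`` per client;
    each client's pre-tax resources are ``w + pd_payoff``.  The punish
    decision applies the strategy's ``(a_coop, a_def)`` bits to the client's
    realized action, each decision passed through the mistake channel.
    """
    a_coop, a_def, _, _ = strategy.bits
    payoffs, punished_flags = [], []
    revenue = 0.0
    cost = 0.0
    for action, pd in client_results:
        pretax = params.w + pd
        revenue += params.tau * pretax
        prescribed = a_coop if action == COOPERATE else a_def
        punished = bool(realize_action(prescribed, params.mu, rng))
        punished_flags.append(punished)
        payoffs.append((1 - params.tau) * pretax - (params.p if punished else 0.0))
        if punished:
            cost += params.v
    return EnforcementOutcome(tuple(payoffs), tuple(punished_flags), revenue, cost)


def meta_payoffs(
    action_i: str, action_j: str, R_i: float, R_j: float, params: ModelParameters
) -> tuple[float, float]:
    """Meta-enforcement payoffs for one enforcer pair.

    Peace on both sides keeps the revenues; a unilateral attacker grabs a
    fraction ``psi`` of the victim's revenue while the victim additionally
    loses ``l``; mutual attack destroys ``l`` on each side with no transfer.
    """
    if action_i == PEACE and action_j == PEACE:
        return R_i, R_j
    if action_i == ATTACK and action_j == PEACE:
        return R_i + params.psi * R_j, (1 - params.psi) * R_j - params.l
    if action_i == PEACE and action_j == ATTACK:
        return (1 - params.psi) * R_i - params.l, R_j + params.psi * R_i
    return R_i - params.l, R_j - params.l


@dataclass
class RoundRecord:
    """Everything that happened in one round, by agent id."""

    producer_pairs: list[tuple[int, int]]
    pair_enforcers: list[int]
    enforcer_pairs: list[tuple[int, int]]
    unmatched: list[int]
    actions: dict[int, object]
    revenues: dict[int, float]
    payoffs: dict[int, float]
    conducts: dict[int, RoundConduct] = field(default_factory=dict)


def _prescribed_attack(strategy: StrategyCode, coplayer_standings: dict[str, str]) -> str:
    _, _, a_good, a_bad = strategy.bits
    if strategy.system is None:
        bit = a_good  # == a_bad: never consults standing
    else:
        bit = a_bad if coplayer_standings.get(strategy.system) == BAD else a_good
    return ATTACK if bit else PEACE


def play_round(
    state: PopulationState,
    ledger: StandingLedger,
    params: ModelParameters,
    rng: np.random.Generator,
) -> RoundRecord:
    """Play one full round and update the ledger in place."""
    producers = state.producer_ids
    enforcers = state.enforcer_ids
    strat_of = {int(i): state.strategy_set[state.assignment[i]] for i in range(state.N)}

    payoffs: dict[int, float] = {}
    actions: dict[int, object] = {}
    revenues: dict[int, float] = {int(e): 0.0 for e in enforcers}
    costs: dict[int, float] = {int(e): 0.0 for e in enforcers}
    npunished: dict[int, int] = {int(e): 0 for e in enforcers}
    client_log: dict[int, list[tuple[str, bool]]] = {int(e): [] for e in enforcers}
    unmatched: list[int] = []

    # -- step 1 + 2: production, taxation, punishment ----------------------
    order = rng.permutation(producers)
    producer_pairs: list[tuple[int, int]] = []
    pair_enforcers: list[int] = []
    if len(order) % 2 == 1:
        lone = int(order[-1])
        unmatched.append(lone)
        payoffs[lone] = params.w  # untaxed autarky production
        order = order[:-1]
    for k in range(0, len(order), 2):
        i, j = int(order[k]), int(order[k + 1])
        producer_pairs.append((i, j))
        a_i = realize_action(strat_of[i].producer_action, params.mu, rng)
        a_j = realize_action(strat_of[j].producer_action, params.mu, rng)
        actions[i], actions[j] = a_i, a_j
        results = [(a_i, pd_payoff(a_i, a_j, params)), (a_j, pd_payoff(a_j, a_i, params))]
        if len(enforcers) == 0:
            pair_enforcers.append(-1)
            payoffs[i] = params.w + results[0][1]
            payoffs[j] = params.w + results[1][1]
            continue
        e = int(enforcers[rng.integers(len(enforcers))])
        pair_enforcers.append(e)
        out = enforcement_outcome(results, strat_of[e], None, params, rng)
        payoffs[i], payoffs[j] = out.client_payoffs
        revenues[e] += out.revenue
        costs[e] += out.cost
        npunished[e] += sum(out.punished)
        client_log[e].extend(
            (action, punished) for (action, _), punished in zip(results, out.punished)
        )

    # -- step 3: meta-enforcement ------------------------------------------
    entry_standings = {int(e): ledger.standings(int(e)) for e in enforcers}
    meta_log: dict[int, Optional[MetaConduct]] = {int(e): None for e in enforcers}
    meta_income: dict[int, float] = {int(e): revenues[int(e)] for e in enforcers}
    eorder = rng.permutation(enforcers)
    enforcer_pairs: list[tuple[int, int]] = []
    if len(eorder) % 2 == 1:
        unmatched.append(int(eorder[-1]))
        eorder = eorder[:-1]
    for k in range(0, len(eorder), 2):
        i, j = int(eorder[k]), int(eorder[k + 1])
        enforcer_pairs.append((i, j))
        act_i = realize_action(
            _prescribed_attack(strat_of[i], entry_standings[j]), params.mu, rng
        )
        act_j = realize_action(
            _prescribed_attack(strat_of[j], entry_standings[i]), params.mu, rng
        )
        actions[i], actions[j] = act_i, act_j
        meta_income[i], meta_income[j] = meta_payoffs(
            act_i, act_j, revenues[i], revenues[j], params
        )
        meta_log[i] = MetaConduct(entry_standings[j], act_i == ATTACK)
        meta_log[j] = MetaConduct(entry_standings[i], act_j == ATTACK)

    # -- settle enforcer payoffs and conduct -------------------------------
    conducts: dict[int, RoundConduct] = {}
    complied: dict[int, dict[str, bool]] = {}
    for e in (int(x) for x in enforcers):
        strategy = strat_of[e]
        payoffs[e] = (
            meta_income[e] - costs[e] - (params.f if strategy.informed else 0.0)
        )
        conduct = RoundConduct(tuple(client_log[e]), meta_log[e])
        conducts[e] = conduct
        complied[e] = {
            sys: COMPLIANCE_BY_SYSTEM[sys](conduct) for sys in ledger.systems
        }
    ledger.record_round(complied)

    return RoundRecord(
        producer_pairs=producer_pairs,
        pair_enforcers=pair_enforcers,
        enforcer_pairs=enforcer_pairs,
        unmatched=unmatched,
        actions=actions,
        revenues=revenues,
        payoffs=payoffs,
        conducts=conducts,
    )
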