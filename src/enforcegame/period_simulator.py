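"""One period: a repeated game of geometrically many rounds.

After every round a new round begins with probability ``delta``, so the
number of rounds ``T`` is geometric with mean ``1/(1 - delta)``.  An
agent's period payoff is her per-round average.  All enforcers start the
period in good standing under every active reputation system; standings
do not persist across periods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core_types import ModelParameters, PopulationState, active_systems
from .reputation import StandingLedger
from .stage_game import play_round

#: Marker for strategies with no users in a period (distinct from a zero payoff).
NO_OBSERVATION = None


def expected_period_length(delta: float) -> float:
    """Mean number of rounds, ``1/(1 - delta)``."""
    if not 0 <= delta < 1:
        raise ValueError(f"delta must lie in [0, 1), got {delta}")
    return 1.0 / (1.0 - delta)


@dataclass
class PeriodResult:
    """Realized length, per-agent period averages, and per-strategy summaries."""

    T: int
    agent_averages: np.ndarray
    strategy_averages: dict[str, Optional[float]]
    counts: dict[str, int]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-agent and per-strategy tables."""
        agents = pd.DataFrame(
            {"agent": np.arange(len(self.agent_averages)), "average_payoff": self.agent_averages}
        )
        strategies = pd.DataFrame(
            {
                "strategy": list(self.strategy_averages),
                "users": [self.counts[s] for s in self.strategy_averages],
                "average_payoff": [self.strategy_averages[s] for s in self.strategy_averages],
            }
        )
        return agents, strategies


def play_period(
    state: PopulationState,
    params: ModelParameters,
    rng: np.random.Generator,
    max_rounds: Optional[int] = None,
) -> PeriodResult:
    """Play rounds until the geometric stop and average each agent's payoffs.

    The stop is drawn round by round (a new round w.p. ``delta``); there is
    no cap unless ``max_rounds`` is given (testing aid only).
    """
    ledger = StandingLedger(
        (int(i) for i in state.enforcer_ids),
        active_systems(state.strategy_set),
        params.kappa,
    )
    totals = np.zeros(state.N)
    T = 0
    while True:
        record = play_round(state, ledger, params, rng)
        for agent, pay in record.payoffs.items():
            totals[agent] += pay
        T += 1
        if max_rounds is not None and T >= max_rounds:
            break
        if rng.random() >= params.delta:
            break
    averages = totals / T

    counts: dict[str, int] = {s.label: 0 for s in state.strategy_set}
    sums: dict[str, float] = {s.label: 0.0 for s in state.strategy_set}
    for agent, k in enumerate(state.assignment):
        label = state.strategy_set[k].label
        counts[label] += 1
        sums[label] += averages[agent]
    strategy_averages = {
        label: (sums[label] / n if n > 0 else NO_OBSERVATION) for label, n in counts.items()
    }
    return PeriodResult(T=T, agent_averages=averages, strategy_averages=strategy_averages, counts=counts)


def strategy_average_payoffs(result: PeriodResult) -> dict[str, Optional[float]]:
    """Realized average payoff per strategy; ``None`` marks no observation."""
    return dict(result.strategy_averages)
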