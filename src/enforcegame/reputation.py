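"""Enforcer reputation: standing scores and compliance standards.

Every enforcer carries a score ``z`` in ``{0, ..., kappa}`` under each
active reputation system.  ``z = 0`` means good standing; ``z > 0`` means
the enforcer is in bad standing and sanctioned for the next ``z`` rounds.
Compliance is judged once per enforcer per round, against the *realized*
actions (after execution mistakes):

- the **CE standard** requires punishing exactly the defecting clients and
  attacking the meta coplayer if and only if that coplayer is in bad CE
  standing;
- the **PE standard** ignores how clients are treated and requires attacking
  the coplayer if and only if that coplayer is in bad PE standing.

A compliant round leaves good standing untouched and reduces a positive
score by one; any violation resets the score to ``kappa``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_types import CE_SYSTEM, COOPERATE, DEFECT, PE_SYSTEM

GOOD = "good"
BAD = "bad"


@dataclass(frozen=True)
class MetaConduct:
    """What one enforcer did in the meta-enforcement step of one round.

    ``coplayer_standing`` maps each active system to the coplayer's standing
    at round entry ("good"/"bad").
    """

    coplayer_standing: dict[str, str]
    attacked: bool


@dataclass(frozen=True)
class RoundConduct:
    """Evidence on which one enforcer's compliance is judged for one round.

    ``clients`` lists ``(realized client PD action, punished?)`` pairs and may
    be empty (the enforcer drew no producer pair that round).  ``meta`` is
    ``None`` when the enforcer was unmatched in the meta-enforcement step.
    """

    clients: tuple[tuple[str, bool], ...] = ()
    meta: Optional[MetaConduct] = None


def _meta_clause(conduct: RoundConduct, system: str, coplayer_standing: Optional[str]) -> bool:
    if conduct.meta is None:
        return True  # vacuous: no meta interaction to judge
    standing = coplayer_standing
    if standing is None:
        standing = conduct.meta.coplayer_standing.get(system)
    if standing not in (GOOD, BAD):
        raise ValueError(f"coplayer standing under {system} must be 'good' or 'bad', got {standing!r}")
    return conduct.meta.attacked == (standing == BAD)


def ce_compliant(conduct: RoundConduct, coplayer_ce_standing: Optional[str] = None) -> bool:
    """Did the enforcer comply with the CE standard this round?

    True iff every defecting client was punished, no cooperating client was
    punished, and the coplayer was attacked exactly if in bad CE standing.
    Clauses with no evidence (no clients, unmatched meta step) hold vacuously.
    """
    for action, punished in conduct.clients:
        if action == DEFECT and not punished:
            return False
        if action == COOPERATE and punished:
            return False
    return _meta_clause(conduct, CE_SYSTEM, coplayer_ce_standing)


def pe_compliant(conduct: RoundConduct, coplayer_pe_standing: Optional[str] = None) -> bool:
    """Did the enforcer comply with the PE standard this round?

    Client treatment is ignored; only the attack decision is judged.
    """
    return _meta_clause(conduct, PE_SYSTEM, coplayer_pe_standing)


COMPLIANCE_BY_SYSTEM = {CE_SYSTEM: ce_compliant, PE_SYSTEM: pe_compliant}


def update_score(z: int, complied: bool, kappa: int) -> int:
    """One step of the score automaton.

    Compliance keeps ``z = 0`` at zero and decrements a positive score;
    any violation resets to ``kappa``.
    """
    if not 0 <= z <= kappa:
        raise ValueError(f"score {z} outside {{0, ..., {kappa}}}")
    if not complied:
        return kappa
    return z - 1 if z > 0 else 0


class StandingLedger:
    """Per-enforcer scores under every active reputation system.

    All enforcers start a period in good standing under every system, and
    every enforcer is scored under every active system regardless of whether
    its own strategy consults that system.  Pass ``track_history=True`` to
    retain a per-round tidy log for debugging.
    """

    def __init__(
        self,
        agent_ids: Iterable[int],
        systems: Sequence[str],
        kappa: int,
        track_history: bool = False,
    ):
        self.systems = tuple(systems)
        self.kappa = int(kappa)
        self.scores: dict[tuple[int, str], int] = {
            (i, sys): 0 for i in agent_ids for sys in self.systems
        }
        self.round = 0
        self.track_history = track_history
        self.history: list[tuple[int, int, str, int]] = []

    def score(self, agent: int, system: str) -> int:
        return self.scores[(agent, system)]

    def standing(self, agent: int, system: str) -> str:
        return BAD if self.scores[(agent, system)] > 0 else GOOD

    def standings(self, agent: int) -> dict[str, str]:
        return {sys: self.standing(agent, sys) for sys in self.systems}

    def ensure(self, agent_ids: Iterable[int]) -> None:
        """Register agents (e.g. after a role switch), starting in good standing."""
        for i in agent_ids:
            for sys in self.systems:
                self.scores.setdefault((i, sys), 0)

    def record_round(self, complied: dict[int, dict[str, bool]]) -> None:
        """Apply one round of score updates from per-enforcer compliance verdicts."""
        self.round += 1
        for agent, by_system in complied.items():
            for sys in self.systems:
                z = update_score(self.scores[(agent, sys)], by_system[sys], self.kappa)
                self.scores[(agent, sys)] = z
                if self.track_history:
                    self.history.append((self.round, agent, sys, z))

    def reset(self) -> None:
        for key in self.scores:
            self.scores[key] = 0
        self.round = 0
        self.history.clear()

    def to_frame(self) -> pd.DataFrame:
        """Tidy snapshot/history table: (round, enforcer, system, score)."""
        if self.track_history and self.history:
            rows = self.history
        else:
            rows = [(self.round, i, sys, z) for (i, sys), z in sorted(self.scores.items())]
        return pd.DataFrame(rows, columns=["round", "enforcer", "system", "score"])
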