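"""Parameter record, strategy encoding, and population state.

The model populates a society of ``N`` agents with two occupations.
*Producers* pair up to play a prisoner's dilemma (benefit ``b``, cost
``c``) on top of an autarky payoff ``w``.  *Enforcers* tax producer
pairs at rate ``tau``, may punish clients (loss ``p`` to the client,
variable cost ``v`` to the enforcer), and meet each other in a
meta-enforcement step where they can fight over tax revenue (attacker
grabs a fraction ``psi``, the attacked party loses ``l``).  Informed
enforcers pay a fixed per-round information cost ``f``.

An enforcer strategy is a four-bit conditional action table

    (a_coop, a_def, a_good, a_bad)

read as: punish a cooperating client / punish a defecting client /
attack a coplayer in good standing / attack a coplayer in bad standing,
where standing is supplied by a reputation system (CE or PE standard,
see :mod:`enforcegame.reputation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

PRODUCER = "producer"
ENFORCER = "enforcer"

COOPERATE = "C"
DEFECT = "D"

CE_SYSTEM = "CE"
PE_SYSTEM = "PE"


class ParameterError(ValueError):
    """A model parameter violates its mathematical domain."""


class StrategyError(ValueError):
    """A strategy literal or code is malformed."""


@dataclass(frozen=True)
class ModelParameters:
    """All model constants, validated on construction.

    ``gamma`` is the triple ``(gamma_pe, gamma_e, gamma_p)`` of revision-class
    probabilities: with probability ``gamma_p`` a producer revises among
    producer strategies, with ``gamma_e`` an enforcer revises among enforcer
    strategies, and with ``gamma_pe`` an agent drawn from the whole population
    revises over the full strategy set.
    """

    b: float
    c: float
    w: float
    tau: float
    p: float
    v: float
    f: float
    l: float
    psi: float
    delta: float
    kappa: int
    mu: float
    eta: float
    epsilon: float
    gamma: tuple[float, float, float]
    N: int

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ParameterError(f"b must be positive, got {self.b}")
        if not self.c > 0:
            raise ParameterError(f"c must be positive, got {self.c}")
        if not self.c < self.b:
            raise ParameterError(
                f"need c < b for a social dilemma, got c={self.c}, b={self.b}"
            )
        if not self.w > 0:
            raise ParameterError(f"w must be positive, got {self.w}")
        if not 0 < self.tau < 1:
            raise ParameterError(f"tau must lie in (0, 1), got {self.tau}")
        if self.p < 0:
            raise ParameterError(f"p must be non-negative, got {self.p}")
        if self.v < 0:
            raise ParameterError(f"v must be non-negative, got {self.v}")
        if not self.tau * self.w > self.v:
            raise ParameterError(
                "need tau*w > v (positive tax revenue), got "
                f"tau*w={self.tau * self.w} <= v={self.v}"
            )
        if self.f < 0:
            raise ParameterError(f"f must be non-negative, got {self.f}")
        if self.l < 0:
            raise ParameterError(f"l must be non-negative, got {self.l}")
        if not 0 <= self.psi <= 1:
            raise ParameterError(f"psi must lie in [0, 1], got {self.psi}")
        if not 0 <= self.delta < 1:
            raise ParameterError(f"delta must lie in [0, 1), got {self.delta}")
        if int(self.kappa) != self.kappa or self.kappa < 1:
            raise ParameterError(f"kappa must be an integer >= 1, got {self.kappa}")
        if not 0 <= self.mu < 0.5:
            raise ParameterError(f"mu must lie in [0, 1/2), got {self.mu}")
        if self.eta < 0:
            raise ParameterError(f"eta must be non-negative, got {self.eta}")
        if not 0 <= self.epsilon <= 1:
            raise ParameterError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        g = tuple(float(x) for x in self.gamma)
        if len(g) != 3 or any(x < 0 for x in g):
            raise ParameterError(f"gamma must be three non-negative weights, got {self.gamma}")
        if abs(sum(g) - 1.0) > 1e-9:
            raise ParameterError(f"gamma must sum to 1, got sum={sum(g)}")
        object.__setattr__(self, "gamma", g)
        if int(self.N) != self.N or self.N < 4:
            raise ParameterError(f"N must be an integer >= 4, got {self.N}")
        object.__setattr__(self, "kappa", int(self.kappa))
        object.__setattr__(self, "N", int(self.N))
        if not self.gamma_ordered:
            warnings.warn(
                "revision probabilities do not satisfy gamma_p > gamma_e > gamma_pe; "
                "the model's standard behavioural assumption is relaxed",
                stacklevel=2,
            )

    @property
    def gamma_pe(self) -> float:
        return self.gamma[0]

    @property
    def gamma_e(self) -> float:
        return self.gamma[1]

    @property
    def gamma_p(self) -> float:
        return self.gamma[2]

    @property
    def gamma_ordered(self) -> bool:
        """Whether gamma_p > gamma_e > gamma_pe (producer revisions easiest)."""
        return self.gamma[2] > self.gamma[1] > self.gamma[0]

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


def validate_params(**raw) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from raw keyword values.

    Raises :class:`ParameterError` on any mathematical-domain violation
    (e.g. ``c >= b``, ``tau`` outside ``(0, 1)``, ``tau*w <= v``, ``gamma``
    not a probability vector).  Violations of the behavioural ordering
    assumption on ``gamma`` only emit a warning, since the model remains
    well defined without it.
    """
    return ModelParameters(**raw)


def baseline_parameters(**overrides) -> ModelParameters:
    """The baseline parameterization (high conflict cost, cheap information)."""
    values = dict(
        b=4.0, c=1.0, w=2.0, tau=0.3, p=2.0, v=0.1, f=0.3, l=5.0,
        psi=0.7, delta=0.9, kappa=8, mu=0.005, eta=0.01, epsilon=0.05,
        gamma=(0.1, 0.3, 0.6), N=50,
    )
    values.update(overrides)
    return ModelParameters(**values)


def alternative_parameters(**overrides) -> ModelParameters:
    """The alternative parameterization (costlier cooperation and information)."""
    values = dict(
        b=3.0, c=2.0, w=2.0, tau=0.3, p=2.0, v=0.3, f=0.4, l=4.0,
        psi=0.7, delta=0.9, kappa=8, mu=0.005, eta=0.01, epsilon=0.05,
        gamma=(0.1, 0.3, 0.6), N=50,
    )
    values.update(overrides)
    return ModelParameters(**values)


@dataclass(frozen=True)
class StrategyCode:
    """One strategy: a producer action or an enforcer conditional-action table.

    Enforcer strategies whose attack action does not depend on standing
    (``a_good == a_bad``) never consult any reputation system; they are
    canonicalized to ``system=None`` so that, e.g., the never-punish
    always-attack strategy is one and the same object regardless of which
    reputation system the surrounding strategy set is named under.
    """

    role: str
    producer_action: Optional[str] = None
    bits: Optional[tuple[int, int, int, int]] = None
    system: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role == PRODUCER:
            if self.producer_action not in (COOPERATE, DEFECT):
                raise StrategyError(
                    f"producer strategy needs producer_action 'C' or 'D', got {self.producer_action!r}"
                )
            if self.bits is not None or self.system is not None:
                raise StrategyError("producer strategies carry no bits/system")
        elif self.role == ENFORCER:
            if self.producer_action is not None:
                raise StrategyError("enforcer strategies carry no producer_action")
            if self.bits is None or len(self.bits) != 4 or any(x not in (0, 1) for x in self.bits):
                raise StrategyError(f"enforcer bits must be a 0/1 quadruple, got {self.bits!r}")
            object.__setattr__(self, "bits", tuple(int(x) for x in self.bits))
            if self.bits[2] == self.bits[3]:
                # never consults standing -> system is meaningless
                object.__setattr__(self, "system", None)
            elif self.system not in (CE_SYSTEM, PE_SYSTEM):
                raise StrategyError(
                    "standing-conditioning enforcer strategy needs system 'CE' or 'PE', "
                    f"got {self.system!r} for bits {self.bits}"
                )
        else:
            raise StrategyError(f"unknown role {self.role!r}")

    # -- derived properties -------------------------------------------------

    @property
    def is_producer(self) -> bool:
        return self.role == PRODUCER

    @property
    def is_enforcer(self) -> bool:
        return self.role == ENFORCER

    @property
    def informed(self) -> bool:
        """Whether the strategy conditions on anything and hence pays ``f``.

        True exactly when the punish action depends on the client's action or
        the attack action depends on the coplayer's standing.
        """
        if self.is_producer:
            return False
        a_coop, a_def, a_good, a_bad = self.bits
        return a_coop != a_def or a_good != a_bad

    @property
    def bitstring(self) -> Optional[str]:
        if self.bits is None:
            return None
        return "".join(str(x) for x in self.bits)

    @property
    def label(self) -> str:
        if self.is_producer:
            return "CP" if self.producer_action == COOPERATE else "DP"
        named = {
            (CE_SYSTEM, (0, 1, 0, 1)): "CE",
            (PE_SYSTEM, (0, 0, 0, 1)): "PE",
            (None, (0, 0, 1, 1)): "DE",
        }
        key = (self.system, self.bits)
        if key in named:
            return named[key]
        if self.system is None:
            return self.bitstring
        return f"{self.system}:{self.bitstring}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    # -- constructors -------------------------------------------------------

    @classmethod
    def producer(cls, action: str) -> "StrategyCode":
        return cls(role=PRODUCER, producer_action=action)

    @classmethod
    def enforcer(cls, bits: Sequence[int], system: Optional[str] = None) -> "StrategyCode":
        return cls(role=ENFORCER, bits=tuple(bits), system=system)

    @classmethod
    def parse(cls, text: str) -> "StrategyCode":
        """Parse a strategy literal.

        Accepted forms: the aliases ``CP``, ``DP``, ``CE``, ``DE``, ``PE``;
        a bare four-bit string like ``0011`` (only for strategies that do not
        consult standing); and a tagged form like ``CE:0101`` or ``PE:0001``.
        """
        t = text.strip().upper()
        aliases = {
            "CP": cls.producer(COOPERATE),
            "DP": cls.producer(DEFECT),
            "CE": cls.enforcer((0, 1, 0, 1), CE_SYSTEM),
            "DE": cls.enforcer((0, 0, 1, 1)),
            "PE": cls.enforcer((0, 0, 0, 1), PE_SYSTEM),
        }
        if t in aliases:
            return aliases[t]
        system = None
        bits_part = t
        if ":" in t:
            sys_part, bits_part = t.split(":", 1)
            if sys_part not in (CE_SYSTEM, PE_SYSTEM):
                raise StrategyError(f"unknown reputation system {sys_part!r} in {text!r}")
            system = sys_part
        if len(bits_part) != 4 or any(ch not in "01" for ch in bits_part):
            raise StrategyError(f"cannot parse strategy literal {text!r}")
        bits = tuple(int(ch) for ch in bits_part)
        if bits[2] != bits[3] and system is None:
            raise StrategyError(
                f"strategy {text!r} conditions on standing; tag it with a system, e.g. 'CE:{bits_part}'"
            )
        return cls.enforcer(bits, system)


CP = StrategyCode.producer(COOPERATE)
DP = StrategyCode.producer(DEFECT)
CE = StrategyCode.enforcer((0, 1, 0, 1), CE_SYSTEM)
DE = StrategyCode.enforcer((0, 0, 1, 1))
PE = StrategyCode.enforcer((0, 0, 0, 1), PE_SYSTEM)

STRATEGY_PRESETS = ("CE16", "CE2", "PE16", "PE2", "CEPE3")


def _sixteen(system: str) -> list[StrategyCode]:
    out = []
    for code in range(16):
        bits = tuple((code >> (3 - k)) & 1 for k in range(4))
        sys_tag = system if bits[2] != bits[3] else None
        out.append(StrategyCode.enforcer(bits, sys_tag))
    return out


def build_strategy_set(preset: str) -> list[StrategyCode]:
    """Return the strategy set for a named preset, producers first.

    Producers are always ``[CP, DP]``.  The enforcer side is:

    - ``CE16``/``PE16``: all 16 four-bit strategies under the named system,
    - ``CE2``: the complying enforcer and the defecting enforcer,
    - ``PE2``: the parochial enforcer and the defecting enforcer,
    - ``CEPE3``: the complying, parochial, and defecting enforcers
      (both reputation systems active).
    """
    enforcers = {
        "CE16": lambda: _sixteen(CE_SYSTEM),
        "PE16": lambda: _sixteen(PE_SYSTEM),
        "CE2": lambda: [CE, DE],
        "PE2": lambda: [PE, DE],
        "CEPE3": lambda: [CE, PE, DE],
    }
    if preset not in enforcers:
        raise StrategyError(
            f"unknown strategy-set preset {preset!r}; choose one of {STRATEGY_PRESETS}"
        )
    return [CP, DP] + enforcers[preset]()


def active_systems(strategies: Iterable[StrategyCode]) -> tuple[str, ...]:
    """Reputation systems consulted by at least one strategy in the set."""
    seen = []
    for s in strategies:
        if s.is_enforcer and s.system is not None and s.system not in seen:
            seen.append(s.system)
    return tuple(sorted(seen))


class PopulationState:
    """Fixed agent identities with one strategy per agent.

    ``assignment[i]`` is the index of agent ``i``'s strategy within
    ``strategy_set``.  Counts and the producer/enforcer split are derived.
    """

    def __init__(self, strategy_set: Sequence[StrategyCode], assignment: Sequence[int]):
        self.strategy_set = list(strategy_set)
        self.assignment = np.asarray(assignment, dtype=np.int64).copy()
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be one strategy index per agent")
        if len(self.assignment) == 0:
            raise ValueError("population must contain at least one agent")
        if self.assignment.min() < 0 or self.assignment.max() >= len(self.strategy_set):
            raise ValueError("assignment indexes outside the strategy set")

    # -- constructors -------------------------------------------------------

    @classmethod
    def random(
        cls, strategy_set: Sequence[StrategyCode], n_agents: int, rng: np.random.Generator
    ) -> "PopulationState":
        """Each agent adopts an i.i.d. uniform draw from the strategy set."""
        return cls(strategy_set, rng.integers(0, len(strategy_set), size=n_agents))

    @classmethod
    def from_counts(
        cls, strategy_set: Sequence[StrategyCode], counts: dict[str, int] | Sequence[int]
    ) -> "PopulationState":
        """Deterministic state with the given number of users per strategy.

        ``counts`` may be a sequence aligned with ``strategy_set`` or a mapping
        from strategy labels to counts (unlisted labels get zero users).
        """
        if isinstance(counts, dict):
            by_label = dict(counts)
            vec = []
            for s in strategy_set:
                vec.append(int(by_label.pop(s.label, 0)))
            if by_label:
                raise StrategyError(f"labels not in strategy set: {sorted(by_label)}")
        else:
            vec = [int(x) for x in counts]
            if len(vec) != len(strategy_set):
                raise ValueError("counts length must match strategy set")
        assignment = np.repeat(np.arange(len(strategy_set)), vec)
        return cls(strategy_set, assignment)

    # -- derived views ------------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.assignment)

    @property
    def strategies(self) -> list[StrategyCode]:
        return [self.strategy_set[k] for k in self.assignment]

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=len(self.strategy_set))

    def counts_by_label(self) -> dict[str, int]:
        return {s.label: int(n) for s, n in zip(self.strategy_set, self.counts)}

    @property
    def producer_ids(self) -> np.ndarray:
        mask = np.array([self.strategy_set[k].is_producer for k in self.assignment])
        return np.flatnonzero(mask)

    @property
    def enforcer_ids(self) -> np.ndarray:
        mask = np.array([self.strategy_set[k].is_enforcer for k in self.assignment])
        return np.flatnonzero(mask)

    @property
    def n_P(self) -> int:
        return len(self.producer_ids)

    @property
    def n_E(self) -> int:
        return len(self.enforcer_ids)

    def copy(self) -> "PopulationState":
        return PopulationState(self.strategy_set, self.assignment)

    def with_strategy(self, agent: int, strategy_index: int) -> "PopulationState":
        new = self.copy()
        new.assignment[agent] = strategy_index
        return new

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(f"{k}={v}" for k, v in self.counts_by_label().items() if v)
        return f"PopulationState(N={self.N}, {parts})"
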