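"""Closed-form results for the repeated enforcement game.

All formulas here are derived in the analytical regime: no action
mistakes (``mu = 0``), no variable punishment cost (``v = 0``), exact
best response (``eta = 0``), and the limits ``delta -> 1`` and
``kappa -> infinity``.  In that regime the unperturbed best-reply
dynamic has two absorbing sets: a cooperation equilibrium (all
producers cooperate, all enforcers comply with the CE standard) with
enforcer fraction

    alpha_C = tau (w + b - c) / (w + b + f - c),

and a defection equilibrium (all producers defect, all enforcers are
defecting enforcers in mutual conflict) with enforcer fraction

    alpha_D = tau w / (w + l).

Both fractions equalize producer and enforcer payoffs within their
equilibrium.  The basin of attraction of each absorbing set is
characterized by how the share of complying enforcers compares with
``f / l``, and a simple criterion in ``(l, f, w, b, c)`` determines
which equilibrium retains the long-run mass as revision mistakes
vanish (stochastic stability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_types import ModelParameters, PopulationState

E_C_BASIN = "E_C_basin"
E_D_BASIN = "E_D_basin"
BOUNDARY_BAND = "boundary_band"

COOPERATION = "cooperation"
DEFECTION = "defection"
BOUNDARY = "boundary"


def alpha_cooperation(params: ModelParameters) -> float:
    """Enforcer fraction in the cooperation equilibrium."""
    s = params.w + params.b - params.c
    denom = s + params.f
    if denom <= 0:
        raise ZeroDivisionError("w + b + f - c must be positive")
    return params.tau * s / denom


def alpha_defection(params: ModelParameters) -> float:
    """Enforcer fraction in the defection equilibrium."""
    denom = params.w + params.l
    if denom <= 0:
        raise ZeroDivisionError("w + l must be positive")
    return params.w * params.tau / denom


@dataclass(frozen=True)
class StaticConditions:
    """The two inequalities that support the fully cooperative equilibrium.

    ``conflict``: the loss from being attacked exceeds twice the larger of
    the information and punishment costs (``l > 2 max{f, v}``), so standing
    is worth protecting.  ``deterrence``: punishment outweighs the after-tax
    gain from defecting (``p > (1 - tau) c``).  ``deterrence_strict`` reports
    the stricter pre-tax reading ``p > c / (1 - tau)`` for reference.
    """

    conflict: bool
    deterrence: bool
    combined: bool
    deterrence_strict: bool


def check_static_conditions(params: ModelParameters) -> StaticConditions:
    conflict = params.l > 2 * max(params.f, params.v)
    deterrence = params.p > (1 - params.tau) * params.c
    strict = params.p > params.c / (1 - params.tau)
    return StaticConditions(
        conflict=conflict,
        deterrence=deterrence,
        combined=conflict and deterrence,
        deterrence_strict=strict,
    )


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the stochastic-stability criterion.

    ``verdict`` is "cooperation", "defection", or "boundary" (exact
    equality).  ``lhs``/``rhs`` are the two sides of

        l/f - 1/(1 + l/w)  vs  1 + f/(w + b - c).

    ``preconditions_ok`` flags whether ``p > (1 - tau) c`` and ``f < l``
    hold; ``v_ignored`` flags that the criterion was evaluated with a
    positive variable punishment cost, which the analytic derivation sets
    to zero.
    """

    verdict: str
    lhs: float
    rhs: float
    preconditions_ok: bool
    v_ignored: bool


def stochastic_stability(params: ModelParameters) -> StabilityResult:
    """Which equilibrium keeps almost all long-run mass as mistakes vanish."""
    preconditions_ok = (params.p > (1 - params.tau) * params.c) and (params.f < params.l)
    if params.f == 0:
        # costless information: cooperation wins in the limit
        return StabilityResult(COOPERATION, math.inf, float("nan"), preconditions_ok, params.v > 0)
    lhs = params.l / params.f - 1.0 / (1.0 + params.l / params.w)
    rhs = 1.0 + params.f / (params.w + params.b - params.c)
    if lhs > rhs:
        verdict = COOPERATION
    elif lhs < rhs:
        verdict = DEFECTION
    else:
        verdict = BOUNDARY
    return StabilityResult(verdict, lhs, rhs, preconditions_ok, params.v > 0)


@dataclass(frozen=True)
class EquilibriumProfile:
    """Equilibrium enforcer fractions and the absorbing integer brackets at size N."""

    alpha_C: float
    alpha_D: float
    e_c_bracket: tuple[float, float]
    e_d_bracket: tuple[float, float]
    e_c_counts: tuple[int, ...]
    e_d_counts: tuple[int, ...]
    producer_payoff_C: float
    enforcer_payoff_C: float
    producer_payoff_D: float
    enforcer_payoff_D: float


def _bracket_counts(lo: float, hi: float, n_max: int) -> tuple[int, ...]:
    return tuple(n for n in range(n_max + 1) if lo <= n <= hi)


def absorbing_brackets(params: ModelParameters) -> EquilibriumProfile:
    """Absorbing-set description at population size ``params.N``.

    The cooperation set contains the states with all producers cooperating,
    all enforcers complying, and ``alpha_C N - 1 <= n_CE <= alpha_C N``; the
    defection set is the analogue with ``alpha_D``.
    """
    aC, aD = alpha_cooperation(params), alpha_defection(params)
    N = params.N
    pay = equilibrium_payoffs(params)
    return EquilibriumProfile(
        alpha_C=aC,
        alpha_D=aD,
        e_c_bracket=(aC * N - 1, aC * N),
        e_d_bracket=(aD * N - 1, aD * N),
        e_c_counts=_bracket_counts(aC * N - 1, aC * N, N),
        e_d_counts=_bracket_counts(aD * N - 1, aD * N, N),
        producer_payoff_C=pay.producer_C,
        enforcer_payoff_C=pay.enforcer_C,
        producer_payoff_D=pay.producer_D,
        enforcer_payoff_D=pay.enforcer_D,
    )


@dataclass(frozen=True)
class EquilibriumPayoffs:
    """Per-round payoffs in each equilibrium at the equalizing enforcer fractions."""

    producer_C: float
    enforcer_C: float
    producer_D: float
    enforcer_D: float
    cooperation_dominates: bool
    alpha_ordered: bool


def equilibrium_payoffs(params: ModelParameters) -> EquilibriumPayoffs:
    """Payoffs in the two equilibria, plus the welfare-comparison flags.

    In the cooperation equilibrium every producer earns
    ``(1 - tau)(w + b - c)`` and enforcers earn the matching taxed surplus
    net of the information cost; in the defection equilibrium producers
    earn ``(1 - tau) w`` and enforcers fight over taxed autarky output.
    By construction of the alphas, payoffs are equalized across occupations
    within each equilibrium.
    """
    aC, aD = alpha_cooperation(params), alpha_defection(params)
    s = params.w + params.b - params.c
    producer_C = (1 - params.tau) * s
    enforcer_C = params.tau * s * (1 - aC) / aC - params.f
    producer_D = (1 - params.tau) * params.w
    enforcer_D = params.tau * params.w * (1 - aD) / aD - params.l
    return EquilibriumPayoffs(
        producer_C=producer_C,
        enforcer_C=enforcer_C,
        producer_D=producer_D,
        enforcer_D=enforcer_D,
        cooperation_dominates=(producer_C > producer_D and enforcer_C > enforcer_D),
        alpha_ordered=aC > aD,
    )


def classify_basin(state_or_counts, params: ModelParameters, n_e: int | None = None) -> str:
    """Which absorbing set an initial state is attracted to.

    Accepts either a :class:`PopulationState` or the pair ``(n_CE, n_E)``
    (as two positional/keyword integers).  The labels partition the state
    space:

    - ``E_C_basin`` iff ``n_CE > (f/l)(n_E - 1) + 1``,
    - ``E_D_basin`` iff ``n_CE < (f/l)(n_E - 1)`` or ``n_E < 2``,
    - ``boundary_band`` otherwise, i.e. when
      ``(n_CE - 1)/(n_E - 1) <= f/l <= n_CE/(n_E - 1)`` with ``n_E >= 2``;
      from the band, either absorbing set is reached with positive
      probability.
    """
    if isinstance(state_or_counts, PopulationState):
        state = state_or_counts
        n_ce = sum(
            int(n)
            for s, n in zip(state.strategy_set, state.counts)
            if s.is_enforcer and s.label == "CE"
        )
        n_e = state.n_E
    else:
        n_ce = int(state_or_counts)
        if n_e is None:
            raise TypeError("classify_basin(n_ce, params, n_e=...) needs the enforcer count")
        n_e = int(n_e)
    if params.l <= 0:
        raise ZeroDivisionError("basin classification needs l > 0")
    if n_e < 2:
        return E_D_BASIN
    ratio = params.f / params.l
    threshold = ratio * (n_e - 1)
    if n_ce > threshold + 1:
        return E_C_BASIN
    if n_ce < threshold:
        return E_D_BASIN
    return BOUNDARY_BAND


def scan_grid(base: ModelParameters, parameter: str, values) -> "pd.DataFrame":
    """Evaluate the closed-form quantities along a one-parameter grid."""
    import pandas as pd

    rows = []
    for value in values:
        p = base.replace(**{parameter: value})
        cond = check_static_conditions(p)
        stab = stochastic_stability(p)
        rows.append(
            {
                parameter: value,
                "alpha_C": alpha_cooperation(p),
                "alpha_D": alpha_defection(p),
                "conflict_condition": cond.conflict,
                "deterrence_condition": cond.deterrence,
                "stability_verdict": stab.verdict,
            }
        )
    return pd.DataFrame(rows)
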