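"""Compiled simulation engine.

This module mirrors the readable implementations in
:mod:`enforcegame.stage_game`, :mod:`enforcegame.period_simulator` and
:mod:`enforcegame.learning_dynamics` as a single numba kernel operating
on integer-coded strategy tables, so that invariant-distribution
estimates over millions of periods stay cheap.  The model semantics are
identical to the reference path (the random streams differ); the test
suite checks the two paths against each other both exactly (the
deterministic analytic payoffs) and statistically (simulated share
trajectories).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numba import njit

from .core_types import (
    CE_SYSTEM,
    COOPERATE,
    PE_SYSTEM,
    ModelParameters,
    StrategyCode,
)

# float parameter vector layout
_B, _C, _W, _TAU, _P, _V, _F, _L, _PSI, _DELTA, _MU, _ETA, _EPS, _GPE, _GE, _GP = range(16)


def strategy_arrays(strategy_set: Sequence[StrategyCode]) -> tuple[np.ndarray, ...]:
    """Integer-coded strategy table: role, producer action, bits, system, informed."""
    S = len(strategy_set)
    role = np.zeros(S, dtype=np.uint8)  # 1 = enforcer
    coop = np.zeros(S, dtype=np.uint8)
    bc = np.zeros(S, dtype=np.uint8)
    bd = np.zeros(S, dtype=np.uint8)
    bg = np.zeros(S, dtype=np.uint8)
    bb = np.zeros(S, dtype=np.uint8)
    sysa = np.zeros(S, dtype=np.int8)  # 0 none, 1 CE, 2 PE
    informed = np.zeros(S, dtype=np.uint8)
    for k, s in enumerate(strategy_set):
        if s.is_producer:
            coop[k] = 1 if s.producer_action == COOPERATE else 0
        else:
            role[k] = 1
            bc[k], bd[k], bg[k], bb[k] = s.bits
            sysa[k] = 1 if s.system == CE_SYSTEM else (2 if s.system == PE_SYSTEM else 0)
            informed[k] = 1 if s.informed else 0
    return role, coop, bc, bd, bg, bb, sysa, informed


def params_vector(params: ModelParameters) -> np.ndarray:
    return np.array(
        [
            params.b, params.c, params.w, params.tau, params.p, params.v,
            params.f, params.l, params.psi, params.delta, params.mu,
            params.eta, params.epsilon,
            params.gamma[0], params.gamma[1], params.gamma[2],
        ],
        dtype=np.float64,
    )


@njit(cache=True)
def _hyp_payoff(s, counts, role, coop, bc, bd, bg, bb, sysa, informed, fp):
    """Analytic expected per-round payoff (mu=0, delta->1, kappa->inf regime)."""
    S = role.shape[0]
    n_p = 0
    n_cp = 0
    n_e = 0
    for x in range(S):
        if role[x] == 0:
            n_p += counts[x]
            if coop[x] == 1:
                n_cp += counts[x]
        else:
            n_e += counts[x]
    n_dp = n_p - n_cp
    b, c, w, tau, p, v, f, l, psi = fp[_B], fp[_C], fp[_W], fp[_TAU], fp[_P], fp[_V], fp[_F], fp[_L], fp[_PSI]

    if role[s] == 0:
        if n_p < 2:
            return w
        a = coop[s]
        partner_coop = (n_cp - a) / (n_p - 1)
        pd = b * partner_coop - c * a
        punish = 0.0
        if n_e > 0:
            tot = 0.0
            for x in range(S):
                if role[x] == 1:
                    bit = bc[x] if a == 1 else bd[x]
                    tot += counts[x] * bit
            punish = tot / n_e
        return (1.0 - tau) * (w + pd) - p * punish

    # long-run standings: grow the bad set monotonically to its fixed point
    bad = np.zeros((S, 2), dtype=np.uint8)
    changed = True
    while changed:
        changed = False
        for x in range(S):
            if role[x] == 0 or counts[x] == 0:
                continue
            vce = 0
            vpe = 0
            if n_p >= 2:
                if n_cp > 0 and bc[x] == 1:
                    vce = 1
                if n_dp > 0 and bd[x] == 0:
                    vce = 1
            if n_e >= 2:
                for y in range(S):
                    if role[y] == 0:
                        continue
                    avail = counts[y] - (1 if y == x else 0)
                    if avail <= 0:
                        continue
                    if sysa[x] == 1:
                        tb = bad[y, 0]
                    elif sysa[x] == 2:
                        tb = bad[y, 1]
                    else:
                        tb = np.uint8(0)
                    att = bb[x] if tb == 1 else bg[x]
                    if att != bad[y, 0]:
                        vce = 1
                    if att != bad[y, 1]:
                        vpe = 1
            if vce == 1 and bad[x, 0] == 0:
                bad[x, 0] = 1
                changed = True
            if vpe == 1 and bad[x, 1] == 0:
                bad[x, 1] = 1
                changed = True

    if n_p >= 2 and n_e > 0:
        R = tau * (n_p * w + (b - c) * n_cp) / n_e
        v_cost = v * (bc[s] * n_cp + bd[s] * n_dp) / n_e
    else:
        R = 0.0
        v_cost = 0.0
    meta = 0.0
    if n_e >= 2:
        for y in range(S):
            if role[y] == 0:
                continue
            avail = counts[y] - (1 if y == s else 0)
            if avail <= 0:
                continue
            q = avail / (n_e - 1)
            if sysa[s] == 1:
                tb = bad[y, 0]
            elif sysa[s] == 2:
                tb = bad[y, 1]
            else:
                tb = np.uint8(0)
            att_i = bb[s] if tb == 1 else bg[s]
            if sysa[y] == 1:
                mb = bad[s, 0]
            elif sysa[y] == 2:
                mb = bad[s, 1]
            else:
                mb = np.uint8(0)
            att_j = bb[y] if mb == 1 else bg[y]
            if att_i == 1 and att_j == 1:
                adj = -l
            elif att_i == 1:
                adj = psi * R
            elif att_j == 1:
                adj = -psi * R - l
            else:
                adj = 0.0
            meta += q * adj
    pay = R + meta - v_cost
    if informed[s] == 1:
        pay -= f
    return pay


@njit(cache=True)
def _chain_kernel(
    assign, role, coop, bc, bd, bg, bb, sysa, informed, fp,
    kappa, ce_active, pe_active, periods, seed, record_every, rec,
    prod_menu, enf_menu, share_sums, final_counts,
):
    np.random.seed(seed)
    N = assign.shape[0]
    S = role.shape[0]
    b, c, w, tau, p, v, f, l, psi = fp[_B], fp[_C], fp[_W], fp[_TAU], fp[_P], fp[_V], fp[_F], fp[_L], fp[_PSI]
    delta, mu, eta, eps = fp[_DELTA], fp[_MU], fp[_ETA], fp[_EPS]
    g_e, g_p = fp[_GE], fp[_GP]

    counts = np.zeros(S, dtype=np.int64)
    for i in range(N):
        counts[assign[i]] += 1

    prod_idx = np.empty(N, dtype=np.int64)
    enf_idx = np.empty(N, dtype=np.int64)
    totals = np.empty(N, dtype=np.float64)
    scores = np.zeros((N, 2), dtype=np.int64)
    revenue = np.empty(N, dtype=np.float64)
    vcost = np.empty(N, dtype=np.float64)
    income = np.empty(N, dtype=np.float64)
    client_ok = np.empty(N, dtype=np.uint8)
    meta_ok_ce = np.empty(N, dtype=np.uint8)
    meta_ok_pe = np.empty(N, dtype=np.uint8)
    strat_sum = np.empty(S, dtype=np.float64)
    strat_pay = np.empty(S, dtype=np.float64)
    menu_pay = np.empty(S, dtype=np.float64)
    adj_counts = np.empty(S, dtype=np.int64)

    rec_i = 0
    for t in range(periods):
        for s in range(S):
            share_sums[s] += counts[s] / N
        if record_every > 0 and t % record_every == 0:
            for s in range(S):
                rec[rec_i, s] = counts[s]
            rec_i += 1

        # role split for this period
        n_p = 0
        n_e = 0
        for i in range(N):
            if role[assign[i]] == 1:
                enf_idx[n_e] = i
                n_e += 1
            else:
                prod_idx[n_p] = i
                n_p += 1

        # ---------------- play one period ----------------
        for i in range(N):
            totals[i] = 0.0
            scores[i, 0] = 0
            scores[i, 1] = 0
        T = 0
        while True:
            T += 1
            # production + enforcement
            for k in range(n_p - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = prod_idx[k]
                prod_idx[k] = prod_idx[j]
                prod_idx[j] = tmp
            for k in range(n_e):
                e = enf_idx[k]
                revenue[e] = 0.0
                vcost[e] = 0.0
                client_ok[e] = 1
                meta_ok_ce[e] = 1
                meta_ok_pe[e] = 1
            if n_p % 2 == 1 and n_p > 0:
                totals[prod_idx[n_p - 1]] += w  # unmatched producer: untaxed autarky
            for k in range(0, n_p - 1, 2):
                i = prod_idx[k]
                j = prod_idx[k + 1]
                ai = coop[assign[i]]
                if mu > 0.0 and np.random.random() < mu:
                    ai = 1 - ai
                aj = coop[assign[j]]
                if mu > 0.0 and np.random.random() < mu:
                    aj = 1 - aj
                pre_i = w + b * aj - c * ai
                pre_j = w + b * ai - c * aj
                if n_e == 0:
                    totals[i] += pre_i
                    totals[j] += pre_j
                    continue
                e = enf_idx[np.random.randint(0, n_e)]
                se = assign[e]
                revenue[e] += tau * (pre_i + pre_j)
                pi = bc[se] if ai == 1 else bd[se]
                if mu > 0.0 and np.random.random() < mu:
                    pi = 1 - pi
                pj = bc[se] if aj == 1 else bd[se]
                if mu > 0.0 and np.random.random() < mu:
                    pj = 1 - pj
                totals[i] += (1.0 - tau) * pre_i - p * pi
                totals[j] += (1.0 - tau) * pre_j - p * pj
                vcost[e] += v * (pi + pj)
                if pi != 1 - ai:
                    client_ok[e] = 0
                if pj != 1 - aj:
                    client_ok[e] = 0
            # meta-enforcement
            for k in range(n_e - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = enf_idx[k]
                enf_idx[k] = enf_idx[j]
                enf_idx[j] = tmp
            for k in range(n_e):
                income[enf_idx[k]] = revenue[enf_idx[k]]
            for k in range(0, n_e - 1, 2):
                i = enf_idx[k]
                j = enf_idx[k + 1]
                jbad_ce = 1 if scores[j, 0] > 0 else 0
                jbad_pe = 1 if scores[j, 1] > 0 else 0
                ibad_ce = 1 if scores[i, 0] > 0 else 0
                ibad_pe = 1 if scores[i, 1] > 0 else 0
                si = assign[i]
                sj = assign[j]
                if sysa[si] == 1:
                    cop_bad = jbad_ce
                elif sysa[si] == 2:
                    cop_bad = jbad_pe
                else:
                    cop_bad = 0
                att_i = bb[si] if cop_bad == 1 else bg[si]
                if mu > 0.0 and np.random.random() < mu:
                    att_i = 1 - att_i
                if sysa[sj] == 1:
                    cop_bad = ibad_ce
                elif sysa[sj] == 2:
                    cop_bad = ibad_pe
                else:
                    cop_bad = 0
                att_j = bb[sj] if cop_bad == 1 else bg[sj]
                if mu > 0.0 and np.random.random() < mu:
                    att_j = 1 - att_j
                if att_i == 1 and att_j == 1:
                    income[i] = revenue[i] - l
                    income[j] = revenue[j] - l
                elif att_i == 1:
                    income[i] = revenue[i] + psi * revenue[j]
                    income[j] = (1.0 - psi) * revenue[j] - l
                elif att_j == 1:
                    income[j] = revenue[j] + psi * revenue[i]
                    income[i] = (1.0 - psi) * revenue[i] - l
                meta_ok_ce[i] = 1 if att_i == jbad_ce else 0
                meta_ok_pe[i] = 1 if att_i == jbad_pe else 0
                meta_ok_ce[j] = 1 if att_j == ibad_ce else 0
                meta_ok_pe[j] = 1 if att_j == ibad_pe else 0
            # settle enforcer payoffs and update scores
            for k in range(n_e):
                i = enf_idx[k]
                si = assign[i]
                pay = income[i] - vcost[i]
                if informed[si] == 1:
                    pay -= f
                totals[i] += pay
                if ce_active == 1:
                    ok = client_ok[i] == 1 and meta_ok_ce[i] == 1
                    z = scores[i, 0]
                    scores[i, 0] = kappa if not ok else (z - 1 if z > 0 else 0)
                if pe_active == 1:
                    ok = meta_ok_pe[i] == 1
                    z = scores[i, 1]
                    scores[i, 1] = kappa if not ok else (z - 1 if z > 0 else 0)
            if np.random.random() >= delta:
                break

        # realized per-strategy average payoffs
        for s in range(S):
            strat_sum[s] = 0.0
        for i in range(N):
            strat_sum[assign[i]] += totals[i] / T
        for s in range(S):
            if counts[s] > 0:
                strat_pay[s] = strat_sum[s] / counts[s]

        # ---------------- one revision ----------------
        u = np.random.random()
        cls = 2
        if u < g_p:
            cls = 0
        elif u < g_p + g_e:
            cls = 1
        if cls == 0 and n_p == 0:
            cls = 2
        if cls == 1 and n_e == 0:
            cls = 2
        if cls == 0:
            agent = prod_idx[np.random.randint(0, n_p)]
            menu = prod_menu
        elif cls == 1:
            agent = enf_idx[np.random.randint(0, n_e)]
            menu = enf_menu
        else:
            agent = np.random.randint(0, N)
            menu = np.arange(S)
        nm = menu.shape[0]
        cur = assign[agent]
        if np.random.random() < eps:
            new = menu[np.random.randint(0, nm)]
        else:
            for k in range(nm):
                m = menu[k]
                if counts[m] > 0:
                    menu_pay[k] = strat_pay[m]
                else:
                    for s in range(S):
                        adj_counts[s] = counts[s]
                    adj_counts[cur] -= 1
                    adj_counts[m] += 1
                    menu_pay[k] = _hyp_payoff(
                        m, adj_counts, role, coop, bc, bd, bg, bb, sysa, informed, fp
                    )
            if eta <= 0.0:
                mx = menu_pay[0]
                for k in range(1, nm):
                    if menu_pay[k] > mx:
                        mx = menu_pay[k]
                nties = 0
                for k in range(nm):
                    if menu_pay[k] == mx:
                        nties += 1
                pick = np.random.randint(0, nties)
                new = menu[0]
                seen = 0
                for k in range(nm):
                    if menu_pay[k] == mx:
                        if seen == pick:
                            new = menu[k]
                            break
                        seen += 1
            else:
                mx = menu_pay[0]
                for k in range(1, nm):
                    if menu_pay[k] > mx:
                        mx = menu_pay[k]
                zsum = 0.0
                for k in range(nm):
                    menu_pay[k] = np.exp((menu_pay[k] - mx) / eta)
                    zsum += menu_pay[k]
                uu = np.random.random() * zsum
                acc = 0.0
                new = menu[nm - 1]
                for k in range(nm):
                    acc += menu_pay[k]
                    if uu < acc:
                        new = menu[k]
                        break
        assign[agent] = new
        counts[cur] -= 1
        counts[new] += 1

    for s in range(S):
        final_counts[s] = counts[s]
    return rec_i


def run_chain(
    assignment: np.ndarray,
    strategy_set: Sequence[StrategyCode],
    params: ModelParameters,
    periods: int,
    seed: int,
    record_every: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the compiled chain; returns (recorded counts, share averages, final assignment)."""
    role, coop, bc, bd, bg, bb, sysa, informed = strategy_arrays(strategy_set)
    fp = params_vector(params)
    S = len(strategy_set)
    systems = {s.system for s in strategy_set if s.is_enforcer and s.system}
    ce_active = 1 if CE_SYSTEM in systems else 0
    pe_active = 1 if PE_SYSTEM in systems else 0
    prod_menu = np.array([k for k, s in enumerate(strategy_set) if s.is_producer], dtype=np.int64)
    enf_menu = np.array([k for k, s in enumerate(strategy_set) if s.is_enforcer], dtype=np.int64)
    if record_every > 0:
        n_rec = (periods + record_every - 1) // record_every
    else:
        n_rec = 1
    rec = np.zeros((n_rec, S), dtype=np.int64)
    share_sums = np.zeros(S, dtype=np.float64)
    final_counts = np.zeros(S, dtype=np.int64)
    assign = np.ascontiguousarray(assignment, dtype=np.int64).copy()
    rec_i = _chain_kernel(
        assign, role, coop, bc, bd, bg, bb, sysa, informed, fp,
        params.kappa, ce_active, pe_active, periods, seed,
        record_every if record_every > 0 else 0, rec,
        prod_menu, enf_menu, share_sums, final_counts,
    )
    return rec[:rec_i], share_sums / periods, assign


def hypothetical_payoff_fast(
    strategy_index: int,
    counts: np.ndarray,
    strategy_set: Sequence[StrategyCode],
    params: ModelParameters,
) -> float:
    """Compiled analytic payoff, for cross-checking against the reference path."""
    role, coop, bc, bd, bg, bb, sysa, informed = strategy_arrays(strategy_set)
    return float(
        _hyp_payoff(
            strategy_index,
            np.asarray(counts, dtype=np.int64),
            role, coop, bc, bd, bg, bb, sysa, informed,
            params_vector(params),
        )
    )
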