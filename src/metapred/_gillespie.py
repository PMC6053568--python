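"""Numba-compiled core of the exact stochastic simulation (direct-method SSA).

State lives in integer per-patch vectors H, P.  Per-patch total rates are
maintained incrementally: after every event only the one or two affected
patches are recomputed.  Deterministic timed entries (state recording and
interventions) are merged into the event loop by truncating the exponential
waiting time at the next scheduled time, the standard treatment for
time-inhomogeneous schedules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event indices (order matches simulator.EVENT_KINDS)
EV_H_BIRTH = 0
EV_H_CROWDING_DEATH = 1
EV_H_BACKGROUND_DEATH = 2
EV_PREDATION = 3
EV_P_BIRTH = 4
EV_P_BACKGROUND_DEATH = 5
EV_H_EMIGRATION = 6
EV_P_EMIGRATION = 7

# scheduled-entry kinds
SCHED_RECORD = 0
SCHED_SET_H = 1
SCHED_SET_P = 2
SCHED_ADD_H = 3
SCHED_ADD_P = 4

STATUS_OK = 0
STATUS_POP_CAP = 1


@njit(cache=False)
def _patch_rate(
    rates, H, P, i,
    g_H, k_H, e_P, H0, a_P, m_H, m_P,
    d_H_max, tau_H, s_H, d_P_max, tau_P, s_P, demog,
):
    h = float(H[i])
    p = float(P[i])
    fr = e_P * h / (h + H0) if h > 0.0 else 0.0
    rates[0] = g_H * h
    rates[1] = g_H * h * h / k_H
    rates[2] = m_H * h
    rates[3] = fr * p
    if demog == 1:
        rates[4] = a_P * fr * p
        rates[5] = m_P * p
    else:
        rates[4] = 0.0
        rates[5] = 0.0
    rates[6] = h * d_H_max / (1.0 + np.exp(-s_H * (h - tau_H)))
    rates[7] = p * d_P_max / (1.0 + np.exp(s_P * (h - tau_P)))
    total = 0.0
    for k in range(8):
        total += rates[k]
    return total


@njit(cache=False)
def simulate_core(
    H, P, settle_cum,
    sched_time, sched_kind, sched_patch, sched_value,
    n_records,
    g_H, k_H, e_P, H0, a_P, m_H, m_P,
    d_H_max, tau_H, s_H, d_P_max, tau_P, s_P,
    demog, pop_cap, seed,
):
    """Run the SSA until the last scheduled time.

    Returns (status, out_H, out_P, event_counts, sink_H, sink_P, t_final).
    ``event_counts`` is an (8, N) tally of executed events by kind and patch;
    ``sink_H``/``sink_P`` count emigrants absorbed by the external sink.
    """
    np.random.seed(seed)
    n = H.shape[0]
    rates = np.zeros(8)
    patch_rate = np.zeros(n)
    for i in range(n):
        patch_rate[i] = _patch_rate(
            rates, H, P, i, g_H, k_H, e_P, H0, a_P, m_H, m_P,
            d_H_max, tau_H, s_H, d_P_max, tau_P, s_P, demog,
        )
    total = patch_rate.sum()

    out_h = np.zeros((n_records, n), np.int64)
    out_p = np.zeros((n_records, n), np.int64)
    counts = np.zeros((8, n), np.int64)
    sink_h = 0
    sink_p = 0
    rec = 0
    t = 0.0
    pop = 0
    for i in range(n):
        pop += H[i] + P[i]
    since_refresh = 0
    n_sched = sched_time.shape[0]

    for s_idx in range(n_sched):
        t_next = sched_time[s_idx]
        while True:
            if total <= 1e-13:
                break
            u = np.random.random()
            dt = -np.log(u) / total
            if t + dt >= t_next:
                break
            t = t + dt

            # select patch
            r = np.random.random() * total
            i = n - 1
            acc = 0.0
            for j in range(n):
                acc += patch_rate[j]
                if r < acc:
                    i = j
                    break

            # select event within patch
            _patch_rate(
                rates, H, P, i, g_H, k_H, e_P, H0, a_P, m_H, m_P,
                d_H_max, tau_H, s_H, d_P_max, tau_P, s_P, demog,
            )
            ri = np.random.random() * patch_rate[i]
            ev = 7
            acc2 = 0.0
            for k in range(8):
                acc2 += rates[k]
                if ri < acc2:
                    ev = k
                    break
            counts[ev, i] += 1

            dest = -1
            if ev == EV_H_BIRTH:
                H[i] += 1
                pop += 1
            elif ev <= EV_PREDATION:  # crowding death, background death, predation
                H[i] -= 1
                pop -= 1
            elif ev == EV_P_BIRTH:
                P[i] += 1
                pop += 1
            elif ev == EV_P_BACKGROUND_DEATH:
                P[i] -= 1
                pop -= 1
            else:  # emigration
                ud = np.random.random()
                dest = np.searchsorted(settle_cum[i], ud, side="right")
                if ev == EV_H_EMIGRATION:
                    H[i] -= 1
                    if dest >= n:
                        sink_h += 1
                        pop -= 1
                    else:
                        H[dest] += 1
                else:
                    P[i] -= 1
                    if dest >= n:
                        sink_p += 1
                        pop -= 1
                    else:
                        P[dest] += 1

            if pop > pop_cap:
                return STATUS_POP_CAP, out_h, out_p, counts, sink_h, sink_p, t

            s = _patch_rate(
                rates, H, P, i, g_H, k_H, e_P, H0, a_P, m_H, m_P,
                d_H_max, tau_H, s_H, d_P_max, tau_P, s_P, demog,
            )
            total += s - patch_rate[i]
            patch_rate[i] = s
            if dest >= 0 and dest < n and dest != i:
                s = _patch_rate(
                    rates, H, P, dest, g_H, k_H, e_P, H0, a_P, m_H, m_P,
                    d_H_max, tau_H, s_H, d_P_max, tau_P, s_P, demog,
                )
                total += s - patch_rate[dest]
                patch_rate[dest] = s
            since_refresh += 1
            if since_refresh >= 100_000:
                # periodic full refresh guards against float drift
                total = patch_rate.sum()
                since_refresh = 0

        # scheduled entry at t_next
        t = t_next
        kind = sched_kind[s_idx]
        if kind == SCHED_RECORD:
            for i in range(n):
                out_h[rec, i] = H[i]
                out_p[rec, i] = P[i]
            rec += 1
        else:
            pi = sched_patch[s_idx]
            v = sched_value[s_idx]
            if kind == SCHED_SET_H:
                pop += v - H[pi]
                H[pi] = v
            elif kind == SCHED_SET_P:
                pop += v - P[pi]
                P[pi] = v
            elif kind == SCHED_ADD_H:
                H[pi] += v
                pop += v
            elif kind == SCHED_ADD_P:
                P[pi] += v
                pop += v
            s = _patch_rate(
                rates, H, P, pi, g_H, k_H, e_P, H0, a_P, m_H, m_P,
                d_H_max, tau_H, s_H, d_P_max, tau_P, s_P, demog,
            )
            total += s - patch_rate[pi]
            patch_rate[pi] = s

    return STATUS_OK, out_h, out_p, counts, sink_h, sink_p, t
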