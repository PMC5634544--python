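"""Fixed-step RK4 kernel for the scalar debt equation over one day.

The Poincaré-map machinery (fixed-point searches, mean-debt matching,
parameter sweeps) needs on the order of 10^4 one-day integrations per
scenario.  The debt equation is smooth within each behavioral phase, so a
classical fixed-step RK4 with a breakpoint at the wake->sleep switch attains
global error far below the fixed-point tolerances at 1920 steps/day, and a
jit-compiled kernel removes per-call overhead.  Adaptive integration of the
full (BR, BI) system lives in :mod:`sleepenergy.poincare`; agreement of the
two routes is property-tested.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import BD_FLOOR

#: Default number of RK4 steps per day.
N_STEPS = 1920

TWO_PI = 2.0 * np.pi


@njit(inline="always")
def _f(t, bd, p_W, p_B1, m_C, A, phi, r_W, r_B):
    c = m_C - A * np.sin(TWO_PI * (t + phi))
    return p_W * r_W + r_B * (p_B1 * bd - c * bd / (1.0 + bd * bd))


@njit(inline="always")
def _segment(bd, t0, t1, p_W, p_B1, m_C, A, phi, r_W, r_B, n):
    """Integrate one phase with n RK4 steps; returns (bd_end, area, ok)."""
    h = (t1 - t0) / n
    area = 0.0
    for k in range(n):
        t = t0 + k * h
        k1 = _f(t, bd, p_W, p_B1, m_C, A, phi, r_W, r_B)
        k2 = _f(t + 0.5 * h, bd + 0.5 * h * k1, p_W, p_B1, m_C, A, phi, r_W, r_B)
        k3 = _f(t + 0.5 * h, bd + 0.5 * h * k2, p_W, p_B1, m_C, A, phi, r_W, r_B)
        k4 = _f(t + h, bd + h * k3, p_W, p_B1, m_C, A, phi, r_W, r_B)
        bd_new = bd + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        area += 0.5 * (bd + bd_new) * h
        bd = bd_new
        if not bd > BD_FLOOR:
            return bd, area, False
    return bd, area, True


@njit
def day_map_many(bd0, p_W, p_B1, m_C, A, tst_frac, r_Ww, r_Bw, r_Ws, r_Bs, n_steps):
    """One-day debt map for an array of start debts.

    Returns ``(bd_end, m_bd, ok)`` where ``m_bd`` is the trapezoid-rule
    time average of BD over the day and ``ok`` flags trajectories that
    stayed above the debt floor (failures carry NaN).
    """
    m = bd0.shape[0]
    bd_end = np.empty(m)
    m_bd = np.empty(m)
    ok = np.empty(m, dtype=np.bool_)
    t_sw = 1.0 - tst_frac
    phi = -0.25 + 0.5 * tst_frac
    n_wake = max(4, int(round(n_steps * t_sw))) if t_sw > 0.0 else 0
    n_sleep = max(4, int(round(n_steps * tst_frac))) if tst_frac > 0.0 else 0
    for i in range(m):
        bd = bd0[i]
        area = 0.0
        good = bd > BD_FLOOR
        if good and n_wake > 0:
            bd, a, good = _segment(
                bd, 0.0, t_sw, p_W, p_B1, m_C, A, phi, r_Ww, r_Bw, n_wake
            )
            area += a
        if good and n_sleep > 0:
            bd, a, good = _segment(
                bd, t_sw, 1.0, p_W, p_B1, m_C, A, phi, r_Ws, r_Bs, n_sleep
            )
            area += a
        if good:
            bd_end[i] = bd
            m_bd[i] = area
        else:
            bd_end[i] = np.nan
            m_bd[i] = np.nan
        ok[i] = good
    return bd_end, m_bd, ok


def day_map(bd0, params, n_steps: int = N_STEPS):
    """Vectorized one-day map for a :class:`ModelParameters` scenario."""
    arr = np.atleast_1d(np.asarray(bd0, dtype=np.float64))
    return day_map_many(
        arr,
        params.p_W,
        params.p_B1,
        params.m_C,
        params.A,
        params.tst_frac,
        params.r_Ww,
        params.r_Bw,
        params.r_Ws,
        params.r_Bs,
        n_steps,
    )
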