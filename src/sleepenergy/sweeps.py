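"""Parameter sweeps and multi-day experiments.

Each sweep runs the three-strategy energy-savings protocol over a grid of
one or two parameters and returns a tidy table (one row per grid point).
Rows where no periodic solution exists are kept and flagged rather than
dropped.  The model has no randomness anywhere, so repeated runs are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import NoCycleError
from .model import DayState, daily_reset
from .params import ModelParameters
from .poincare import DayTrajectory, integrate_day
from .strategies import (
    StrategyResult,
    energy_savings,
    match_mean_BD,
    solve_strategy_wake,
)

_ROW_FIELDS = (
    "r_Ww",
    "r_Bw",
    "r_Ws",
    "r_Bs",
    "rho_achieved",
    "mai_target",
    "mai_achieved",
    "m_BD",
    "m_MR",
    "matched",
)


def _nan_row() -> dict:
    row = {k: np.nan for k in _ROW_FIELDS}
    row["matched"] = False
    return row


def _result_row(res: StrategyResult) -> dict:
    return {k: getattr(res, k) for k in _ROW_FIELDS}


@lru_cache(maxsize=512)
def _wake_cached(params: ModelParameters) -> StrategyResult:
    return solve_strategy_wake(params)


@lru_cache(maxsize=512)
def _match_cached(
    baseline_mBD: float, rho: float, mai_target: float, params: ModelParameters
) -> StrategyResult:
    return match_mean_BD(baseline_mBD, rho, mai_target, params)


def _protocol_row(
    params: ModelParameters, rho: float, mai_target: float, tst_h: float
) -> dict:
    """One grid point of a sweep: baseline + both matches + ES split."""
    p = params.with_(TST_h=tst_h)
    row: dict = {"TST_h": tst_h, "rho": rho}
    try:
        wake = _wake_cached(p)
    except NoCycleError:
        row.update(_nan_row())
        row.update(
            has_cycle=False, m_MR1=np.nan, m_MR2=np.nan, m_MR3=np.nan,
            ES_rho=np.nan, ES_MAI=np.nan, ES_total=np.nan,
        )
        row["mai_target"] = mai_target
        return row
    try:
        mr = _match_cached(wake.m_BD, rho, 0.0, p)
        mp = (
            mr
            if mai_target == 0.0
            else _match_cached(wake.m_BD, rho, mai_target, p)
        )
    except NoCycleError:
        row.update(_nan_row())
        row.update(
            has_cycle=False, m_MR1=wake.m_MR, m_MR2=np.nan, m_MR3=np.nan,
            ES_rho=np.nan, ES_MAI=np.nan, ES_total=np.nan,
        )
        row["mai_target"] = mai_target
        return row
    es = energy_savings(wake.m_MR, mr.m_MR, mp.m_MR)
    row.update(_result_row(mp))
    row.update(
        has_cycle=True,
        m_MR1=wake.m_MR,
        m_MR2=mr.m_MR,
        m_MR3=mp.m_MR,
        ES_rho=es.ES_rho,
        ES_MAI=es.ES_MAI,
        ES_total=es.ES_total,
    )
    return row


def sweep_mai(
    mai_grid: Sequence[float],
    rho: float,
    TST_h: float,
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """Energy savings over a grid of target MAI values (fixed rho, TST).

    The non-negativity clamp on the sleep rates caps the achievable MAI, so
    ``mai_achieved`` saturates as the target approaches 1.
    """
    params = params or ModelParameters()
    rows = []
    for mai in mai_grid:
        row = _protocol_row(params, rho, float(mai), TST_h)
        row["mai_target"] = float(mai)
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_tst(
    tst_grid: Sequence[float],
    mai_target: float,
    rho: float,
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """Energy savings over a grid of sleep quotas (fixed MAI target, rho).

    Short quotas favor savings from partitioning; very long quotas shift
    the gains toward metabolic-rate reduction.  Points without a periodic
    solution (expected at small TST) are flagged.
    """
    params = params or ModelParameters()
    return pd.DataFrame(
        [_protocol_row(params, rho, mai_target, float(tst)) for tst in tst_grid]
    )


def sweep_rho(
    rho_grid: Sequence[float],
    mai_target: float,
    TST_h: float,
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """Energy savings over a grid of sleep metabolic-rate reductions.

    Large reductions constrain the achievable MAI (the clamp binds sooner),
    so the partitioning contribution shrinks as rho grows.
    """
    params = params or ModelParameters()
    return pd.DataFrame(
        [_protocol_row(params, float(r), mai_target, TST_h) for r in rho_grid]
    )


def sweep_circadian(
    mai_grid: Sequence[float],
    A_grid: Sequence[float],
    rho: float,
    TST_h: float,
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """Two-dimensional sweep over target MAI and circadian amplitude.

    Amplitude amplifies savings when partitioning is at least moderate and
    erodes them when allocation is state-independent (MAI = 0).
    """
    params = params or ModelParameters()
    rows = []
    for a in A_grid:
        p = params.with_(A=float(a))
        for mai in mai_grid:
            row = _protocol_row(p, rho, float(mai), TST_h)
            row["A"] = float(a)
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_grid(
    pW_grid: Sequence[float],
    pB1_grid: Sequence[float],
    mC_values: Sequence[float],
    params: ModelParameters | None = None,
    *,
    TST_h: float = 8.0,
    rho: float = 0.3,
    mai_target: float = 0.4,
    A_factor: float = 0.5,
) -> pd.DataFrame:
    """Sensitivity of total savings to the price and circadian-mean constants.

    For each ``m_C`` the circadian amplitude is tied as ``A = A_factor*m_C``;
    grid points without a limit cycle are recorded as missing.  The waking
    price must be positive, so ``p_W = 0`` grid entries are nudged to a
    small positive value before construction (the scalar debt equation is
    continuous in ``p_W``).
    """
    params = params or ModelParameters()
    rows = []
    for mc in mC_values:
        for pw in pW_grid:
            for pb1 in pB1_grid:
                p = params.with_(
                    p_W=max(float(pw), 1e-9),
                    p_B1=float(pb1),
                    m_C=float(mc),
                    A=A_factor * float(mc),
                )
                row = _protocol_row(p, rho, mai_target, TST_h)
                row.update(p_W=float(pw), p_B1=float(pb1), m_C=float(mc))
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_sensitivity(table: pd.DataFrame) -> dict:
    """Spread of total savings over grid points admitting a limit cycle."""
    ok = table[table["has_cycle"]]
    per_mc = {
        float(mc): float(g["ES_total"].max() - g["ES_total"].min())
        for mc, g in ok.groupby("m_C")
    }
    return {
        "n_points": int(len(table)),
        "n_with_cycle": int(len(ok)),
        "range_total": float(ok["ES_total"].max() - ok["ES_total"].min()),
        "range_per_mC": per_mc,
    }


@dataclass(frozen=True)
class MultiDayRun:
    """Chained daily trajectories with per-day summaries and flags."""

    days: pd.DataFrame  # columns: day, BD_end, mean_BD
    times: np.ndarray  # global time in days
    BD: np.ndarray
    steady_state: bool
    escalation: bool

    @property
    def n_days(self) -> int:
        return len(self.days)


def multiday_run(
    n_days: int,
    params: ModelParameters,
    BD_init: float,
    *,
    steady_rtol: float = 1e-4,
) -> MultiDayRun:
    """Simulate successive days with fixed rates and the daily reset.

    The debt is continuous across day boundaries (the reset only moves BR
    and BI).  ``steady_state`` is set when the relative change of the daily
    mean debt falls below ``steady_rtol`` at the end of the run;
    ``escalation`` is set when the daily mean grows by increasing
    increments across the final three days — the regime where investment
    can no longer service requirements and homeostasis is escaping.
    """
    if n_days < 2:
        raise ValueError("need at least 2 days")
    state = DayState(t=0.0, BR=float(BD_init), BI=0.0)
    records = []
    all_t, all_bd = [], []
    for day in range(n_days):
        traj = integrate_day(state.BD, params)
        records.append(
            {"day": day + 1, "BD_end": traj.BD_end, "mean_BD": traj.mean_BD}
        )
        all_t.append(traj.times + day)
        all_bd.append(traj.BD)
        state = daily_reset(DayState(t=1.0, BR=traj.BR[-1], BI=traj.BI[-1]))
    days = pd.DataFrame(records)
    means = days["mean_BD"].to_numpy()
    steady = bool(abs(means[-1] - means[-2]) / means[-1] < steady_rtol)
    escalation = False
    if n_days >= 3:
        d1 = means[-2] - means[-3]
        d2 = means[-1] - means[-2]
        escalation = bool(d2 > d1 > 0.0)
    return MultiDayRun(
        days=days,
        times=np.concatenate(all_t),
        BD=np.concatenate(all_bd),
        steady_state=steady and not escalation,
        escalation=escalation,
    )


def bd_shape_metrics(trajectory: DayTrajectory) -> dict:
    """Shape summary of a daily debt curve.

    Reports the overall range, per-phase monotonicity fractions, counts of
    interior local extrema, and a per-phase convexity sign — enough to
    distinguish the flat steady state (no circadian drive, no
    partitioning), the sinusoid-like wave (circadian drive only), and the
    homeostat-like rise-in-wake/fall-in-sleep pattern that appears once
    partitioning is introduced.
    """
    t = trajectory.times
    bd = trajectory.BD
    t_sw = trajectory.params.t_switch
    d = np.diff(bd)
    mid = 0.5 * (t[:-1] + t[1:])
    wake = mid < t_sw
    sleep = ~wake

    def frac_increasing(mask: np.ndarray) -> float:
        if mask.sum() == 0:
            return np.nan
        return float((d[mask] > 0).sum() / mask.sum())

    # interior strict sign changes of the slope
    sgn = np.sign(d)
    nz = sgn[sgn != 0]
    flips = np.diff(nz)
    n_max = int((flips < 0).sum())
    n_min = int((flips > 0).sum())

    def convexity(mask: np.ndarray) -> float:
        if mask.sum() < 3:
            return np.nan
        dd = np.diff(d[mask])
        return float(np.sign(dd.mean()))

    return {
        "bd_range": float(bd.max() - bd.min()),
        "wake_increasing_frac": frac_increasing(wake),
        "sleep_decreasing_frac": 1.0 - frac_increasing(sleep)
        if sleep.sum() > 0
        else np.nan,
        "n_local_max": n_max,
        "n_local_min": n_min,
        "wake_convexity": convexity(wake),
        "sleep_convexity": convexity(sleep),
    }
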