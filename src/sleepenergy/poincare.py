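"""One-day integration, the start-of-day-debt Poincaré map, its fixed points
(daily limit cycles), stability, cycle averages, and the saddle-node
bifurcation in a one-parameter family.

The Poincaré map P sends the debt at the start of a day to the debt at its
end.  Because the scalar debt flow is one-dimensional, P is strictly
increasing; its fixed points are the model's periodic daily solutions.  In
the regimes of interest the map crosses the diagonal zero, once (tangency)
or twice — when two fixed points exist the smaller-debt one is stable (the
map crosses the diagonal from above).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from ._kernel import N_STEPS, day_map
from .exceptions import BifurcationError, InvalidTrajectoryError, NoCycleError
from .params import BD_FLOOR, ModelParameters

#: Default debt interval searched for Poincaré fixed points.  The conversion
#: efficiency decays to zero at large debt, so trajectories diverge well
#: below the upper end for standard parameters.
SEARCH_INTERVAL = (1e-6, 50.0)

#: |P'(BD*) - 1| below this is classified half-stable (tangent cycle).
HALF_STABLE_TOL = 1e-3

STABLE = "stable"
UNSTABLE = "unstable"
HALF_STABLE = "half-stable"


@dataclass(frozen=True)
class DayTrajectory:
    """Sampled solution of the (BR, BI) system over one day."""

    times: np.ndarray
    BR: np.ndarray
    BI: np.ndarray
    params: ModelParameters

    @property
    def BD(self) -> np.ndarray:
        return self.BR - self.BI

    @property
    def BD_end(self) -> float:
        return float(self.BR[-1] - self.BI[-1])

    @property
    def mean_BD(self) -> float:
        """Time average of BD over the day (trapezoid rule)."""
        return float(np.trapezoid(self.BD, self.times))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "BR": self.BR, "BI": self.BI, "BD": self.BD}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LimitCycle:
    """A periodic daily solution: a fixed point of the Poincaré map."""

    BD0: float
    stability: str
    m_BD: float
    trajectory: DayTrajectory | None = None


def integrate_day(
    BD0: float,
    params: ModelParameters,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    n_points: int = 481,
) -> DayTrajectory:
    """Integrate the (BR, BI) pair over one day from a reset state.

    Starts at ``BR = BD0, BI = 0`` and places an integrator breakpoint at
    the wake->sleep switch (the right-hand side is discontinuous there).
    Raises :class:`InvalidTrajectoryError` if the debt reaches its
    positivity floor.
    """
    if not BD0 > 0:
        raise ValueError(f"BD0 must be > 0, got {BD0}")
    p = params
    phi = p.circadian_phase

    def make_rhs(r_W: float, r_B: float) -> Callable:
        def f(t, y):
            bd = y[0] - y[1]
            c = p.m_C - p.A * np.sin(2.0 * np.pi * (t + phi))
            dBR = p.p_W * r_W + p.p_B1 * bd * r_B
            dBI = c * bd / (1.0 + bd * bd) * r_B
            return (dBR, dBI)

        return f

    def floor_event(t, y):
        return (y[0] - y[1]) - BD_FLOOR

    floor_event.terminal = True
    floor_event.direction = -1.0

    if p.tst_frac > 0.0:
        segments = [
            (0.0, p.t_switch, make_rhs(p.r_Ww, p.r_Bw)),
            (p.t_switch, 1.0, make_rhs(p.r_Ws, p.r_Bs)),
        ]
    else:
        segments = [(0.0, 1.0, make_rhs(p.r_Ww, p.r_Bw))]

    times, brs, bis = [], [], []
    y = (float(BD0), 0.0)
    for t0, t1, f in segments:
        n_seg = max(2, int(round(n_points * (t1 - t0))))
        sol = solve_ivp(
            f,
            (t0, t1),
            y,
            t_eval=np.linspace(t0, t1, n_seg),
            rtol=rtol,
            atol=atol,
            events=floor_event,
            dense_output=False,
        )
        if sol.status == 1:  # floor event fired
            raise InvalidTrajectoryError(
                f"debt reached the positivity floor at t={sol.t_events[0][0]:.4f}"
            )
        if not sol.success:
            raise InvalidTrajectoryError(f"integration failed: {sol.message}")
        skip = 1 if times else 0  # drop duplicated breakpoint sample
        times.append(sol.t[skip:])
        brs.append(sol.y[0][skip:])
        bis.append(sol.y[1][skip:])
        y = (sol.y[0][-1], sol.y[1][-1])

    traj = DayTrajectory(
        times=np.concatenate(times),
        BR=np.concatenate(brs),
        BI=np.concatenate(bis),
        params=params,
    )
    if not np.all(traj.BD > BD_FLOOR):
        raise InvalidTrajectoryError("debt reached the positivity floor")
    return traj


def poincare_map(BD0, params: ModelParameters, *, n_steps: int = N_STEPS):
    """One-day Poincaré map of the start-of-day debt.

    Accepts a scalar or an array of start debts.  Scalar input with an
    invalid trajectory raises :class:`InvalidTrajectoryError`; array input
    returns NaN at the failing entries.
    """
    scalar = np.isscalar(BD0) or np.ndim(BD0) == 0
    end, _, ok = day_map(BD0, params, n_steps)
    if scalar:
        if not ok[0]:
            raise InvalidTrajectoryError("debt reached the positivity floor")
        return float(end[0])
    return end


def map_slope(BD0: float, params: ModelParameters, *, h: float = 1e-5) -> float:
    """Centered finite-difference slope of the Poincaré map at ``BD0``."""
    end, _, ok = day_map(np.array([BD0 - h, BD0 + h]), params)
    if not ok.all():
        raise InvalidTrajectoryError("cannot estimate slope: trajectory invalid")
    return float((end[1] - end[0]) / (2.0 * h))


def classify_stability(slope: float) -> str:
    if abs(slope - 1.0) < HALF_STABLE_TOL:
        return HALF_STABLE
    return STABLE if slope < 1.0 else UNSTABLE


def _fixed_points_fast(
    params: ModelParameters,
    search_interval: tuple[float, float] = SEARCH_INTERVAL,
    n_grid: int = 60,
    xtol: float = 1e-8,
) -> list[tuple[float, float, float]]:
    """Locate fixed points of the day map via the jit kernel.

    Returns a sorted list of ``(BD0, slope, m_BD)`` triples.  The grid scan
    is followed by bracketed root-finding on ``P(BD) - BD``; an interior
    positive local minimum of the residual is additionally refined by
    bounded minimization so that barely-existing (near-tangent) cycle pairs
    are not missed.
    """
    lo, hi = search_interval
    grid = np.geomspace(lo, hi, n_grid)
    end, _, ok = day_map(grid, params)
    g = end - grid
    valid = ok & np.isfinite(g)

    def g_scalar(bd: float) -> float:
        e, _, o = day_map(np.array([bd]), params)
        if not o[0]:
            raise InvalidTrajectoryError("trajectory invalid during root search")
        return float(e[0] - bd)

    brackets: list[tuple[float, float]] = []
    for i in range(len(grid) - 1):
        if valid[i] and valid[i + 1] and np.sign(g[i]) != np.sign(g[i + 1]):
            brackets.append((grid[i], grid[i + 1]))

    roots: list[float] = []
    for a, b in brackets:
        roots.append(float(brentq(g_scalar, a, b, xtol=xtol)))

    # near-tangency: refine the interior minimum of the residual
    if not roots:
        interior = [
            i
            for i in range(1, len(grid) - 1)
            if valid[i - 1] and valid[i] and valid[i + 1]
            and g[i] <= g[i - 1] and g[i] <= g[i + 1]
            and g[i - 1] > 0.0 and g[i + 1] > 0.0
        ]
        if interior:
            i = min(interior, key=lambda j: g[j])
            res = minimize_scalar(
                g_scalar, bounds=(grid[i - 1], grid[i + 1]), method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun < 0.0:
                roots.append(float(brentq(g_scalar, grid[i - 1], res.x, xtol=xtol)))
                roots.append(float(brentq(g_scalar, res.x, grid[i + 1], xtol=xtol)))
            elif res.fun < xtol:
                roots.append(float(res.x))  # tangent (half-stable) cycle

    out = []
    for r in sorted(set(roots)):
        if out and abs(r - out[-1][0]) < 1e-6:
            continue
        slope = map_slope(r, params)
        _, mbd, _ = day_map(np.array([r]), params)
        out.append((r, slope, float(mbd[0])))
    return out


def find_fixed_points(
    params: ModelParameters,
    search_interval: tuple[float, float] = SEARCH_INTERVAL,
    *,
    n_grid: int = 60,
    xtol: float = 1e-8,
    with_trajectory: bool = True,
) -> list[LimitCycle]:
    """Find and classify all limit cycles in the search interval.

    Returns 0, 1 or 2 cycles sorted by start debt; an empty list is a valid
    outcome (no periodic solution).  When two exist, the smaller-debt cycle
    is the stable one.
    """
    cycles = []
    for bd0, slope, mbd in _fixed_points_fast(params, search_interval, n_grid, xtol):
        traj = integrate_day(bd0, params) if with_trajectory else None
        m_bd = traj.mean_BD if traj is not None else mbd
        cycles.append(
            LimitCycle(BD0=bd0, stability=classify_stability(slope), m_BD=m_bd,
                       trajectory=traj)
        )
    return cycles


def stable_cycle(
    params: ModelParameters,
    search_interval: tuple[float, float] = SEARCH_INTERVAL,
    **kwargs,
) -> LimitCycle:
    """The (half-)stable limit cycle, or raise :class:`NoCycleError`.

    Half-stable (tangent) cycles are admitted, matching the convention that
    averages are taken over (half-)stable periodic solutions.
    """
    for cyc in find_fixed_points(params, search_interval, **kwargs):
        if cyc.stability in (STABLE, HALF_STABLE):
            return cyc
    raise NoCycleError("no (half-)stable periodic solution in the search interval")


def mean_BD(cycle: LimitCycle | DayTrajectory) -> float:
    """Time-averaged debt over one period of a cycle (or of a trajectory)."""
    if isinstance(cycle, DayTrajectory):
        return cycle.mean_BD
    if cycle.trajectory is not None:
        return cycle.trajectory.mean_BD
    return cycle.m_BD


def iterate_map(
    BD0: float, params: ModelParameters, n_iter: int = 200
) -> np.ndarray:
    """Forward-iterate the Poincaré map; brute-force oracle for stable
    fixed points (the iterates of a stable cycle converge to its BD0)."""
    out = np.empty(n_iter + 1)
    out[0] = BD0
    bd = BD0
    for k in range(n_iter):
        bd = poincare_map(bd, params)
        out[k + 1] = bd
    return out


def find_bifurcation(
    family: Callable[[float], ModelParameters],
    r_range: tuple[float, float] = (0.0, 10.0),
    *,
    xtol: float = 1e-5,
    coarse_step: float = 0.02,
    search_interval: tuple[float, float] = SEARCH_INTERVAL,
) -> tuple[float, LimitCycle]:
    """Locate the saddle-node onset of limit cycles in a one-parameter family.

    ``family(r)`` must return the scenario at parameter value ``r`` (in the
    intended use, the wake investment rate ``r_Bw`` with the sleep rates
    resolved from the targets).  Fixed points must be absent at the low end
    and present at the high end; the smallest ``r`` with an existing fixed
    point is found by bisection to ``xtol`` and the near-tangent cycle there
    is returned.
    """

    def exists(r: float) -> bool:
        return bool(_fixed_points_fast(family(r), search_interval))

    lo, hi = r_range
    if exists(lo):
        raise BifurcationError(f"limit cycle already exists at r={lo}")
    r = lo
    found = None
    while r < hi:
        r = min(r + coarse_step, hi)
        if exists(r):
            found = r
            break
    if found is None:
        raise BifurcationError(
            f"no limit cycle appears anywhere in r range ({lo}, {hi})"
        )
    a, b = found - coarse_step, found
    while b - a > xtol:
        mid = 0.5 * (a + b)
        if exists(mid):
            b = mid
        else:
            a = mid
    params_star = family(b)
    cycles = find_fixed_points(params_star, search_interval)
    stable = [c for c in cycles if c.stability in (STABLE, HALF_STABLE)]
    if not stable:
        raise BifurcationError("tangent cycle lost during refinement")
    return b, stable[0]
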