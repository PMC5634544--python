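"""Energy-savings protocol: derived indices, rate resolution, mean-debt
matching, and the three-strategy comparison.

Two dimensionless indices summarize how the four energy rates relate across
behavioral states:

* ``rho`` — proportional reduction of total metabolic rate from wake to
  sleep: ``rho = 1 - (r_Ws + r_Bs)/(r_Ww + r_Bw)``.
* ``MAI`` — metabolic allocation index, the degree of state-dependent
  partitioning: ``MAI = ((r_Ww - r_Bw)/(r_Ww + r_Bw)
  + (r_Bs - r_Ws)/(r_Ws + r_Bs)) / 2``; 0 means identical allocation ratios
  in both states, 1 means fully partitioned (``r_Bw = r_Ws = 0``).

Savings are quantified against *Strategy Wake* — continuous wakefulness
(TST = 0, equal wake rates) — by requiring every sleep strategy to maintain
the same time-averaged biological debt over its daily limit cycle.  With
``r_Ww`` held fixed, the wake investment rate ``r_Bw`` is adjusted upward
from zero until the stable cycle's mean debt matches the Wake baseline; the
sleep rates follow from the requested ``rho`` and target MAI.  When the
cycle appears (saddle-node onset) with a mean debt already below the
baseline, savings are computed at the bifurcation point instead and the
result is flagged unmatched.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

from scipy.optimize import brentq

from .exceptions import NoCycleError
from .params import ModelParameters
from .poincare import (
    HALF_STABLE,
    STABLE,
    LimitCycle,
    _fixed_points_fast,
    classify_stability,
    find_bifurcation,
    stable_cycle,
)

STRATEGY_WAKE = "Wake"
STRATEGY_MR = "MRReduction"
STRATEGY_MP_MR = "MP+MRReduction"

#: Relative tolerance on the mean-debt match.
MATCH_RTOL = 1e-4


@dataclass(frozen=True)
class StrategyResult:
    """Resolved rates and derived quantities for one strategy."""

    strategy: str
    TST_h: float
    r_Ww: float
    r_Bw: float
    r_Ws: float
    r_Bs: float
    rho_achieved: float
    mai_target: float
    mai_achieved: float
    m_BD: float
    m_MR: float
    matched: bool
    cycle: LimitCycle | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "TST_h": self.TST_h,
            "r_Ww": self.r_Ww,
            "r_Bw": self.r_Bw,
            "r_Ws": self.r_Ws,
            "r_Bs": self.r_Bs,
            "rho_achieved": self.rho_achieved,
            "mai_target": self.mai_target,
            "mai_achieved": self.mai_achieved,
            "m_BD": self.m_BD,
            "m_MR": self.m_MR,
            "matched": self.matched,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class EnergySavings:
    """Savings components in percent of the Wake-strategy mean metabolic rate."""

    ES_rho: float
    ES_MAI: float
    ES_total: float

    def to_dict(self) -> dict:
        return asdict(self)


def rho_of_rates(r_Ww: float, r_Bw: float, r_Ws: float, r_Bs: float) -> float:
    """Proportion of metabolic-rate reduction from wake to sleep."""
    wake_mr = r_Ww + r_Bw
    if wake_mr <= 0:
        raise ZeroDivisionError("wake metabolic rate is zero; rho undefined")
    return 1.0 - (r_Ws + r_Bs) / wake_mr


def mai_of_rates(r_Ww: float, r_Bw: float, r_Ws: float, r_Bs: float) -> float:
    """Metabolic allocation index of four energy rates."""
    wake_mr = r_Ww + r_Bw
    sleep_mr = r_Ws + r_Bs
    if wake_mr <= 0 or sleep_mr <= 0:
        raise ZeroDivisionError("phase metabolic rate is zero; MAI undefined")
    return 0.5 * ((r_Ww - r_Bw) / wake_mr + (r_Bs - r_Ws) / sleep_mr)


def sleep_rates_from_target(
    r_Bw: float, rho: float, mai_target: float, r_Ww: float
) -> tuple[float, float]:
    """Resolve the sleep rates from ``rho`` and a target MAI.

    ``r_Ws = max(0, (1-rho)*((1-MAI)*r_Ww - MAI*r_Bw))`` and
    ``r_Bs = (1-rho)*(r_Ww + r_Bw) - r_Ws``; the clamp keeps all rates
    non-negative, so the achieved MAI can fall short of the target while
    the requested ``rho`` always holds exactly.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if not 0.0 <= mai_target <= 1.0:
        raise ValueError(f"mai_target must be in [0, 1], got {mai_target}")
    r_Ws = max(0.0, (1.0 - rho) * ((1.0 - mai_target) * r_Ww - mai_target * r_Bw))
    r_Bs = (1.0 - rho) * (r_Ww + r_Bw) - r_Ws
    return r_Ws, r_Bs


def mean_MR(scenario: ModelParameters | StrategyResult) -> float:
    """Time-averaged daily metabolic rate:
    ``(1 - TST/24)*(r_Ww + r_Bw) + (TST/24)*(r_Ws + r_Bs)`` (exact
    arithmetic, no integration)."""
    f = scenario.TST_h / 24.0
    return (1.0 - f) * (scenario.r_Ww + scenario.r_Bw) + f * (
        scenario.r_Ws + scenario.r_Bs
    )


def energy_savings(m_MR1: float, m_MR2: float, m_MR3: float) -> EnergySavings:
    """Savings components, in percent of the Wake mean metabolic rate.

    ``ES_rho = (m_MR1 - m_MR2)/m_MR1`` (rate reduction alone),
    ``ES_total = (m_MR1 - m_MR3)/m_MR1`` (partitioning plus reduction),
    ``ES_MAI = ES_total - ES_rho``.
    """
    if m_MR1 <= 0:
        raise ZeroDivisionError("baseline mean metabolic rate must be > 0")
    es_rho = 100.0 * (m_MR1 - m_MR2) / m_MR1
    es_total = 100.0 * (m_MR1 - m_MR3) / m_MR1
    return EnergySavings(ES_rho=es_rho, ES_MAI=es_total - es_rho, ES_total=es_total)


def _mai_achieved(r_Ww, r_Bw, r_Ws, r_Bs) -> float:
    try:
        return mai_of_rates(r_Ww, r_Bw, r_Ws, r_Bs)
    except ZeroDivisionError:
        return math.nan


def solve_strategy_wake(params: ModelParameters) -> StrategyResult:
    """Continuous-wakefulness baseline: TST = 0 with equal wake rates.

    Finds the stable daily limit cycle and records its mean debt (the
    matching target for the sleep strategies) and the baseline mean
    metabolic rate ``m_MR1 = r_Ww + r_Bw``.
    """
    if not math.isclose(params.r_Ww, params.r_Bw, rel_tol=0, abs_tol=1e-12):
        raise ValueError(
            f"Strategy Wake requires r_Ww == r_Bw, got {params.r_Ww} != {params.r_Bw}"
        )
    p = params.with_(TST_h=0.0, r_Ws=params.r_Ww, r_Bs=params.r_Bw)
    cyc = stable_cycle(p)
    return StrategyResult(
        strategy=STRATEGY_WAKE,
        TST_h=0.0,
        r_Ww=p.r_Ww,
        r_Bw=p.r_Bw,
        r_Ws=p.r_Ws,
        r_Bs=p.r_Bs,
        rho_achieved=0.0,
        mai_target=0.0,
        mai_achieved=0.0,
        m_BD=cyc.m_BD,
        m_MR=p.r_Ww + p.r_Bw,
        matched=True,
        cycle=cyc,
    )


def _stable_mbd_fast(params: ModelParameters) -> float | None:
    """Mean debt of the (half-)stable cycle via the jit kernel, else None."""
    for bd0, slope, mbd in _fixed_points_fast(params):
        if classify_stability(slope) in (STABLE, HALF_STABLE):
            return mbd
    return None


def match_mean_BD(
    baseline_mBD: float,
    rho: float,
    mai_target: float,
    params: ModelParameters,
    *,
    r_bw_step: float = 0.02,
    r_bw_max: float = 10.0,
    rtol: float = MATCH_RTOL,
) -> StrategyResult:
    """Resolve a sleep strategy by matching mean debt to the Wake baseline.

    Scans ``r_Bw`` upward from 0 (holding ``r_Ww``), resolving the sleep
    rates from ``rho`` and the MAI target at each step.  Past the
    saddle-node onset the stable cycle's mean debt decreases with ``r_Bw``;
    the match is refined by bracketed root-finding to ``rtol`` (relative on
    mean debt).  If the cycle is born with mean debt already at or below
    the baseline, the result is computed at the bifurcation point and
    flagged ``matched=False``.  Raises :class:`NoCycleError` if no periodic
    solution exists anywhere in the scanned range.
    """
    r_Ww = params.r_Ww

    def scenario(r_Bw: float) -> ModelParameters:
        r_Ws, r_Bs = sleep_rates_from_target(r_Bw, rho, mai_target, r_Ww)
        return params.with_rates(r_Ww, r_Bw, r_Ws, r_Bs)

    def mbd(r_Bw: float) -> float | None:
        return _stable_mbd_fast(scenario(r_Bw))

    def mbd_or_raise(r_Bw: float) -> float:
        m = mbd(r_Bw)
        if m is None:
            raise NoCycleError(
                f"limit cycle vanished during match refinement at r_Bw={r_Bw}"
            )
        return m

    # coarse upward scan for cycle existence and the baseline crossing
    r_no = None  # last r without a cycle before onset
    first = None  # (r, m_BD) at first existence
    above = None  # last (r, m_BD) with m_BD > baseline
    below = None  # first (r, m_BD) with m_BD <= baseline
    r = 0.0
    while r <= r_bw_max + 1e-12:
        m = mbd(r)
        if m is None:
            if first is not None:
                break  # cycle existed and vanished again; stop scanning
            r_no = r
        else:
            if first is None:
                first = (r, m)
            if m > baseline_mBD:
                above = (r, m)
            else:
                below = (r, m)
                break
        r = round(r + r_bw_step, 12)

    if first is None:
        raise NoCycleError(
            f"no periodic solution for any r_Bw in [0, {r_bw_max}] "
            f"(rho={rho}, mai_target={mai_target}, TST={params.TST_h} h)"
        )

    matched = True
    bracket: tuple[float, float] | None = None
    if above is not None and below is not None:
        bracket = (above[0], below[0])
    elif above is not None:
        raise NoCycleError(
            f"mean debt never reaches the baseline for r_Bw <= {r_bw_max}"
        )
    else:
        # first scanned cycle already at/below baseline: examine the onset
        if r_no is None:
            r_final = first[0]  # cycle exists from r_Bw = 0 on
            matched = math.isclose(first[1], baseline_mBD, rel_tol=rtol)
        else:
            r_star, _ = find_bifurcation(
                scenario, (r_no, first[0] + 1e-12), coarse_step=r_bw_step
            )
            m_star = mbd(r_star)
            if m_star is not None and m_star > baseline_mBD:
                bracket = (r_star, first[0])
            else:
                r_final = r_star
                matched = False
    if bracket is not None:
        r_final = float(
            brentq(lambda x: mbd_or_raise(x) - baseline_mBD, *bracket, xtol=1e-8)
        )

    p_final = scenario(float(r_final))
    cyc = stable_cycle(p_final)
    label = STRATEGY_MR if mai_target == 0.0 else STRATEGY_MP_MR
    return StrategyResult(
        strategy=label,
        TST_h=params.TST_h,
        r_Ww=p_final.r_Ww,
        r_Bw=p_final.r_Bw,
        r_Ws=p_final.r_Ws,
        r_Bs=p_final.r_Bs,
        rho_achieved=rho_of_rates(
            p_final.r_Ww, p_final.r_Bw, p_final.r_Ws, p_final.r_Bs
        ),
        mai_target=mai_target,
        mai_achieved=_mai_achieved(
            p_final.r_Ww, p_final.r_Bw, p_final.r_Ws, p_final.r_Bs
        ),
        m_BD=cyc.m_BD,
        m_MR=mean_MR(p_final),
        matched=matched,
        cycle=cyc,
    )


def run_three_strategies(
    params: ModelParameters, rho: float, mai_target: float
) -> tuple[StrategyResult, StrategyResult, StrategyResult, EnergySavings]:
    """Full protocol: Wake baseline, rate-reduction-only, and partitioning
    strategies at the given ``rho`` and MAI target, plus the savings split."""
    wake = solve_strategy_wake(params)
    mr = match_mean_BD(wake.m_BD, rho, 0.0, params)
    mp = match_mean_BD(wake.m_BD, rho, mai_target, params)
    savings = energy_savings(wake.m_MR, mr.m_MR, mp.m_MR)
    return wake, mr, mp, savings
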