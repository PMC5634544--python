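"""Core model functions: circadian multiplier, prices, conversion efficiency,
phase-dependent rates, the within-day right-hand side, and the daily reset.

The state variables are biological requirements (BR), the accumulated
maintenance obligations generated by all metabolic operations, and biological
investment (BI), the accumulated completed maintenance work.  Their difference
is the biological debt BD = BR - BI, the model's homeostatic variable:

    dBR/dt = p_W * r_W(t) + p_B(BD) * r_B(t)
    dBI/dt = x_B(t, BD) * r_B(t)

with price p_B(BD) = p_B1 * BD and conversion efficiency
x_B(t, BD) = C(t) * BD / (1 + BD^2).  Because both right-hand sides depend on
the pair only through BD, the debt obeys the scalar equation

    dBD/dt = p_W * r_W(t) + r_B(t) * (p_B1 * BD - C(t) * BD / (1 + BD^2)).

At the start of each day BI is reset to 0 and BR to the current debt, so BD is
continuous across the reset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidStateError
from .params import ModelParameters

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DayState:
    """Instantaneous model state within a day.

    ``t`` is time within the day in days (in [0, 1]); BR and BI are in
    arbitrary energy-debt units.  The debt BD = BR - BI must stay positive.
    """

    t: float
    BR: float
    BI: float

    @property
    def BD(self) -> float:
        return self.BR - self.BI


def circadian_C(t: float, params: ModelParameters) -> float:
    """Circadian efficiency multiplier C(t).

    A sinusoid with mean ``m_C``, amplitude ``A`` and period one day whose
    peak falls in the middle of the sleep phase:
    ``C(t) = m_C - A*sin(2*pi*(t - 0.25 + 0.5*TST/24))``.
    """
    return params.m_C - params.A * math.sin(TWO_PI * (t + params.circadian_phase))


def price_pB(BD: float, params: ModelParameters) -> float:
    """Price of biological investment, proportional to debt: ``p_B1 * BD``."""
    if BD <= 0:
        raise InvalidStateError(f"biological debt must be > 0, got {BD}")
    return params.p_B1 * BD


def conversion_xB(t: float, BD: float, params: ModelParameters) -> float:
    """Conversion efficiency of the investment stream, ``C(t)*BD/(1+BD^2)``.

    Low at low debt, maximal at BD = 1 (value C(t)/2), and decaying to zero
    as debt grows — a reactive homeostasis in converting energy to
    investment.  Returns the limit value 0 at BD = 0 for robustness.
    """
    if BD < 0:
        raise InvalidStateError(f"biological debt must be >= 0, got {BD}")
    return circadian_C(t, params) * BD / (1.0 + BD * BD)


def phase_rates(t: float, params: ModelParameters) -> tuple[float, float]:
    """Energy rates ``(r_W, r_B)`` in effect at time ``t``.

    The wake rates apply on ``[0, 1 - TST/24)`` and the sleep rates on
    ``[1 - TST/24, 1]``; the switch instant belongs to sleep.  With TST = 0
    there is no sleep phase and the wake rates apply everywhere.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"time must be in [0, 1] days, got {t}")
    if params.tst_frac > 0.0 and t >= params.t_switch:
        return params.r_Ws, params.r_Bs
    return params.r_Ww, params.r_Bw


def rhs(t: float, state: DayState, params: ModelParameters) -> tuple[float, float]:
    """Right-hand side ``(dBR/dt, dBI/dt)`` of the within-day system."""
    bd = state.BD
    if bd <= 0:
        raise InvalidStateError(f"biological debt must be > 0, got {bd}")
    r_W, r_B = phase_rates(t, params)
    dBR = params.p_W * r_W + price_pB(bd, params) * r_B
    dBI = conversion_xB(t, bd, params) * r_B
    return dBR, dBI


def rhs_bd(t: float, BD: float, params: ModelParameters) -> float:
    """Scalar debt equation, the exact reduction of :func:`rhs`:

    ``dBD/dt = p_W*r_W(t) + r_B(t)*(p_B1*BD - C(t)*BD/(1+BD^2))``.
    """
    if BD <= 0:
        raise InvalidStateError(f"biological debt must be > 0, got {BD}")
    r_W, r_B = phase_rates(t, params)
    return params.p_W * r_W + r_B * (params.p_B1 * BD - conversion_xB(t, BD, params))


def daily_reset(end_state: DayState) -> DayState:
    """Start-of-day reset: BI goes to 0, BR to the end-of-day debt.

    The debt itself is continuous across the reset, and the map is
    idempotent on already-reset states.
    """
    return DayState(t=0.0, BR=end_state.BD, BI=0.0)
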