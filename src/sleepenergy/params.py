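"""Parameter set for one scenario of the energy-allocation model.

A scenario is a 24 h day split into a wake phase followed by a sleep phase.
Energy is deployed at constant rates within each phase, toward two streams:
waking effort (``r_W``) and biological investment (``r_B``).  Time is measured
in days, so one period is exactly 1; total sleep time is entered in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

#: Positivity floor for biological debt.  Trajectories that reach it are
#: flagged invalid rather than clamped (the model requires BD > 0).
BD_FLOOR = 1e-12

#: Standard parameter values used throughout (prices, circadian constants).
STANDARD = {"p_W": 1.3, "p_B1": 0.7, "m_C": 5.0, "A": 2.5}

#: Keys of the flat key-value config dialect, in canonical order.
PARAM_KEYS = ("p_W", "p_B1", "m_C", "A", "TST_h", "r_Ww", "r_Bw", "r_Ws", "r_Bs")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for one scenario.

    Parameters
    ----------
    p_W : float
        Price of waking effort (dimensionless multiplier, > 0).
    p_B1 : float
        Proportionality constant of the investment price
        ``p_B(t) = p_B1 * BD(t)`` (dimensionless, >= 0).
    m_C : float
        Circadian mean level (> 0).
    A : float
        Circadian amplitude, half the peak-to-trough range (>= 0, < ``m_C``
        so the efficiency multiplier stays positive).
    TST_h : float
        Total sleep time in hours, in [0, 24).
    r_Ww, r_Bw : float
        Wake-phase energy rates toward waking effort / biological
        investment (energy per day, >= 0).
    r_Ws, r_Bs : float
        Sleep-phase energy rates (energy per day, >= 0).
    """

    p_W: float = STANDARD["p_W"]
    p_B1: float = STANDARD["p_B1"]
    m_C: float = STANDARD["m_C"]
    A: float = STANDARD["A"]
    TST_h: float = 8.0
    r_Ww: float = 0.5
    r_Bw: float = 0.5
    r_Ws: float = 0.5
    r_Bs: float = 0.5

    def __post_init__(self) -> None:
        if not self.p_W > 0:
            raise ValueError(f"p_W must be > 0, got {self.p_W}")
        if self.p_B1 < 0:
            raise ValueError(f"p_B1 must be >= 0, got {self.p_B1}")
        if not self.m_C > 0:
            raise ValueError(f"m_C must be > 0, got {self.m_C}")
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if not self.A < self.m_C:
            raise ValueError(
                f"circadian amplitude A={self.A} must be < m_C={self.m_C} "
                "(the efficiency multiplier C(t) must stay positive)"
            )
        if not 0.0 <= self.TST_h < 24.0:
            raise ValueError(f"TST_h must be in [0, 24), got {self.TST_h}")
        for name in ("r_Ww", "r_Bw", "r_Ws", "r_Bs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def tst_frac(self) -> float:
        """Sleep fraction of the day, TST/24."""
        return self.TST_h / 24.0

    @property
    def t_switch(self) -> float:
        """Wake-to-sleep switch time in days, ``1 - TST/24``.

        Computed as ``(24 - TST_h)/24`` so that round fractions of the day
        (e.g. 2/3 for an 8 h quota) compare exactly in floating point.
        """
        return (24.0 - self.TST_h) / 24.0

    @property
    def circadian_phase(self) -> float:
        """Phase offset of the circadian sinusoid (peak lands mid-sleep)."""
        return -0.25 + 0.5 * self.tst_frac

    def with_(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def with_rates(self, r_Ww: float, r_Bw: float, r_Ws: float, r_Bs: float) -> "ModelParameters":
        """Return a copy with all four energy rates replaced."""
        return replace(self, r_Ww=r_Ww, r_Bw=r_Bw, r_Ws=r_Ws, r_Bs=r_Bs)

    # -- flat key-value serialization -------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with the canonical key names."""
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        """Build from a flat mapping; unknown keys are rejected."""
        unknown = set(data) - set(PARAM_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class PhaseSchedule:
    """Partition of the day into a wake interval followed by sleep.

    The boundary instant belongs to the sleep phase; with ``TST = 0`` the
    sleep interval is empty and the whole day is wake.
    """

    wake_interval: tuple[float, float]
    sleep_interval: tuple[float, float]

    @classmethod
    def from_params(cls, params: ModelParameters) -> "PhaseSchedule":
        ts = params.t_switch
        return cls(wake_interval=(0.0, ts), sleep_interval=(ts, 1.0))

    def phase_of(self, t: float) -> str:
        """Return ``"wake"`` or ``"sleep"`` for a time within the day."""
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"time must be in [0, 1] days, got {t}")
        ts = self.wake_interval[1]
        return "wake" if t < ts else "sleep" if ts < 1.0 else "wake"
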