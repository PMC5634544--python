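"""Shared fixtures.

The expensive objects (Wake baseline, matched strategies, sweeps) are
session-scoped: the model is deterministic, so reuse across tests is safe.
"""

from __future__ import annotations

import numpy as np
import pytest

import sleepenergy as se

# published scenario parameter sets (zero-cycle, cycle-onset, two-cycle regimes)
NO_CYCLE_RATES = (0.5, 0.0, 0.21, 0.14)
ONSET_RATES = (0.5, 0.20079, 0.15378, 0.33678)
TWO_CYCLE_RATES = (0.5, 0.3, 0.126, 0.434)


@pytest.fixture(scope="session")
def standard() -> se.ModelParameters:
    """Standard parameters with an 8 h sleep quota."""
    return se.ModelParameters()


@pytest.fixture(scope="session")
def wake(standard) -> se.StrategyResult:
    """Continuous-wakefulness baseline (stable cycle + mean debt)."""
    return se.solve_strategy_wake(standard)


@pytest.fixture(scope="session")
def mr_reduction(standard, wake) -> se.StrategyResult:
    """Rate-reduction-only strategy at rho=0.3, TST=8."""
    return se.match_mean_BD(wake.m_BD, 0.3, 0.0, standard)


@pytest.fixture(scope="session")
def mp_04(standard, wake) -> se.StrategyResult:
    """Partitioning strategy at MAI target 0.4, rho=0.3, TST=8."""
    return se.match_mean_BD(wake.m_BD, 0.3, 0.4, standard)


@pytest.fixture(scope="session")
def mp_max(standard, wake) -> se.StrategyResult:
    """Partitioning strategy pushed to the MAI clamp (target 1)."""
    return se.match_mean_BD(wake.m_BD, 0.3, 1.0, standard)


@pytest.fixture(scope="session")
def mai_sweep_table(standard):
    """Target-MAI sweep at rho=0.3, TST=8 (step 0.05)."""
    return se.sweep_mai(np.arange(0.0, 1.0 + 1e-9, 0.05), 0.3, 8.0, standard)


@pytest.fixture(scope="session")
def tst_sweep_table(standard):
    """TST sweep at MAI target 0.4, rho=0.3 (1..23 h, step 1)."""
    return se.sweep_tst(np.arange(1.0, 24.0, 1.0), 0.4, 0.3, standard)
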