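"""Exception types raised by the model machinery."""


class SleepEnergyError(Exception):
    """Base class for model-level failures."""


class InvalidStateError(SleepEnergyError):
    """A model state violates an invariant (e.g. biological debt <= 0)."""


class InvalidTrajectoryError(SleepEnergyError):
    """A trajectory left the admissible region (debt hit the positivity floor)."""


class NoCycleError(SleepEnergyError):
    """No (half-)stable periodic solution exists for the requested scenario."""


class BifurcationError(SleepEnergyError):
    """Limit-cycle existence does not change over the searched parameter range."""
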