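"""Exception hierarchy shared across the package."""


class NoisyARError(Exception):
    """Base class for all package-specific errors."""


class StationarityError(NoisyARError, ValueError):
    """Autoregressive (or moving-average) coefficient outside the unit interval."""


class DegenerateProcessError(NoisyARError, ValueError):
    """A process with zero total variance, or chains with no variation."""


class IdentificationError(NoisyARError, ValueError):
    """The requested transformation or model is not identified (e.g. phi = 0)."""


class EstimationFailureError(NoisyARError, RuntimeError):
    """Every optimization attempt failed to produce a usable fit."""
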