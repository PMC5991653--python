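"""Exception hierarchy."""


class FPTimingError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FPTimingError):
    """A parameter set violates a model invariant or a mode is misused."""


class UnreachableThresholdError(FPTimingError):
    """The regulator can never enter a regime where the target is produced,
    so the target threshold cannot be crossed (singular generator)."""


class InfeasibleTargetError(FPTimingError):
    """No production rate can make the mean first-passage time equal the
    target time (e.g. the deterministic regulator crosses its threshold
    after the target time in the step limit)."""


class NoCrossingsError(FPTimingError):
    """An ensemble contains too few threshold crossings to form statistics."""


class BinningError(FPTimingError):
    """Every (threshold, bin width) combination of a bin grid is underpopulated."""
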