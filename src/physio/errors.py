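"""Exception hierarchy shared across the package.

Every error raised by physio derives from :class:`PhysioError`, so callers
can catch a single base class at pipeline boundaries.
"""


class PhysioError(Exception):
    """Base class for all physio errors."""


class InvalidParameterError(PhysioError, ValueError):
    """A generator or estimator received parameters violating its contract."""


class MalformedFileError(PhysioError):
    """An on-disk sweep, stack or table file violates the expected dialect."""


class SignalKindError(PhysioError):
    """An operation received a voltage sweep where a current sweep was
    required, or vice versa."""


class AlreadyCorrectedError(PhysioError):
    """Liquid-junction-potential correction applied twice to the same sweep."""


class NotCorrectedError(PhysioError):
    """A voltage-based estimate was requested on a sweep whose LJP
    correction flag is unset."""


class FitFailureError(PhysioError):
    """A least-squares fit failed to converge within the bounded restarts.

    Carries the final residual (RMS, trace units) when available.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateFitError(FitFailureError):
    """The data cannot constrain the model (e.g. step faster than one
    sample, constant trace)."""


class IntegrationFailureError(PhysioError):
    """The fixed-step integrator diverged; message names the dt used."""


class NoEventError(PhysioError):
    """No suprathreshold event found where at least one was required."""


class NoAHPError(PhysioError):
    """The post-spike trace never undershoots the resting potential."""


class UndefinedLatencyError(PhysioError):
    """Latency statistics requested but zero repetitions were
    suprathreshold."""


class UndefinedRatioError(PhysioError):
    """A ratio whose denominator is zero (white pixel count, first-pulse
    jitter)."""


class InsufficientDepthError(PhysioError):
    """An image stack is too shallow for the requested projection."""


class DegenerateRescaleError(PhysioError):
    """Constant-intensity stack cannot be min-max rescaled to 8 bit."""


class EmptyMaskError(PhysioError):
    """Soma segmentation produced an empty mask."""


class UnimodalHistogramError(PhysioError):
    """In-mask intensity histogram has fewer than two detectable peaks; the
    cell cannot be thresholded by the two-population rule."""


class StatisticsError(PhysioError, ValueError):
    """A statistical routine received an ill-posed sample (too small,
    constant, single group)."""
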