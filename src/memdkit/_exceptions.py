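"""Exception hierarchy shared across the toolkit."""


class MemdkitError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(MemdkitError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateEnvelopeError(MemdkitError):
    """Fewer than two usable spline knots; no envelope can be fitted."""


class NoImfError(MemdkitError):
    """The signal has too few extrema for even one sifting pass."""


class EnvelopeUndefinedError(MemdkitError):
    """No projection direction yields enough maxima; the residual is reached."""


class DegenerateImfError(MemdkitError):
    """An IMF with (near-)zero variance cannot be normalised or scored."""


class UndefinedMetricError(MemdkitError):
    """A metric that needs at least two retained IMFs got fewer."""
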