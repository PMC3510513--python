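"""Exception hierarchy shared across the package."""


class RnpKineticsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RnpKineticsError, ValueError):
    """Invalid domain object or argument (negative rate, malformed scheme, ...)."""


class FitError(RnpKineticsError, RuntimeError):
    """A least-squares fit failed to converge.

    Carries the best attempt found so far (if any) in ``best_attempt`` and the
    SSR trace of the multistart in ``ssr_trace``.
    """

    def __init__(self, message, best_attempt=None, ssr_trace=None):
        super().__init__(message)
        self.best_attempt = best_attempt
        self.ssr_trace = ssr_trace or []


class UnidentifiableError(FitError):
    """The data cannot constrain the requested parameter (e.g. flat titration)."""


class ParseError(RnpKineticsError, ValueError):
    """Malformed input file; the message names the offending row/field."""
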