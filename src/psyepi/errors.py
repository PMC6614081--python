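"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration field is missing, malformed, or inconsistent."""


class DataValidationError(ValueError):
    """An input table violates a structural contract (e.g. discharge before admit)."""


class FittingError(RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
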