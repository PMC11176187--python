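"""Exception types shared across the package."""


class InputShapeError(ValueError):
    """An argument has the wrong length or shape."""


class ParameterError(ValueError):
    """A parameter is outside its valid range."""


class InfeasibleError(ValueError):
    """The requested object does not exist (e.g. a 1-variable non-canalizing core)."""


class ResourceError(RuntimeError):
    """A rejection-sampling cap or a state-space cap was exceeded."""


class RuleParseError(ValueError):
    """A rule file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
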