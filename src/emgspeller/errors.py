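"""Exception hierarchy for the speller pipeline."""


class SpellerError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpellerError):
    """Invalid configuration (filter frequencies, window sizes, gains...)."""


class ScriptError(SpellerError):
    """A gesture script violates its invariants (overlap, negative duration...)."""


class ParseError(SpellerError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationError(SpellerError):
    """Baseline calibration failed (no data, or degenerate all-zero baseline)."""
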