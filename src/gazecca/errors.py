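"""Exception hierarchy for gazecca.

All errors raised by the package derive from :class:`GazeccaError` so callers
can catch everything from one base, while the pipeline distinguishes
participant-level problems (recoverable, logged as exclusions) from
cohort-level ones (fatal).
"""


class GazeccaError(Exception):
    """Base class for all gazecca errors."""


class InvalidParameterError(GazeccaError, ValueError):
    """A simulation or analysis parameter violates its invariants."""


class FormatError(GazeccaError, ValueError):
    """An input file does not conform to the expected dialect."""


class TooShortRecordingError(GazeccaError, ValueError):
    """A gaze recording has too few samples to analyse."""


class LanguageMappingError(GazeccaError, KeyError):
    """A native language is absent from the linguistic-distance table."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class DegenerateInputError(GazeccaError, ValueError):
    """An input is too small or too uniform for the requested operation."""


class DegenerateColumnError(DegenerateInputError):
    """A data column is constant and cannot be standardized."""


class InsufficientSampleError(GazeccaError, ValueError):
    """Too few observations for the requested statistical procedure."""


class NumericalError(GazeccaError, ArithmeticError):
    """A linear-algebra step failed beyond what ridge conditioning repairs."""
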