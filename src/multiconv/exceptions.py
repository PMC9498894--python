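"""Exception hierarchy for multiconv.

All package errors derive from :class:`MulticonvError` so callers can catch
one base class at CLI boundaries.
"""


class MulticonvError(Exception):
    """Base class for all multiconv errors."""


class AlphabetError(MulticonvError, ValueError):
    """A sequence contains a character outside the DNA alphabet {A,C,G,T,N}."""

    def __init__(self, position: int, character: str):
        self.position = position
        self.character = character
        super().__init__(
            f"invalid character {character!r} at position {position}: "
            "expected one of A, C, G, T, N (case-insensitive)"
        )


class NumericError(MulticonvError, ValueError):
    """Non-finite values where finite numbers are required."""


class DimensionError(MulticonvError, ValueError):
    """Shapes or lengths of two operands do not agree."""


class SequenceTooShortError(MulticonvError, ValueError):
    """A sequence is shorter than the kernel scanning it."""


class ConfigError(MulticonvError, ValueError):
    """Invalid configuration value or combination."""


class DataError(MulticonvError, ValueError):
    """Invalid or empty dataset."""


class DivergenceError(MulticonvError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss encountered at epoch {epoch}")


class UndefinedCorrelationError(MulticonvError, ValueError):
    """Rank correlation is undefined (a constant input vector)."""


class DegenerateMotifError(MulticonvError, ValueError):
    """A motif row sums to zero and cannot be normalized."""


class InsufficientDataError(MulticonvError, ValueError):
    """A statistical test was given too few observations."""


class MemeParseError(MulticonvError, ValueError):
    """A MEME motif file is malformed."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class SimulationSpecError(MulticonvError, ValueError):
    """A simulation specification is internally inconsistent."""


class PlacementError(MulticonvError, RuntimeError):
    """Planted motif sites could not be placed without overlap."""
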