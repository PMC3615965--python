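"""Exception hierarchy shared across the package."""


class CppredError(Exception):
    """Base class for all package-specific errors."""


class InvalidResidueError(CppredError):
    """Sequence contains a character outside the 20-letter amino-acid alphabet.

    Attributes
    ----------
    residue : str
        The offending character.
    position : int
        1-based position of the offending character.
    """

    def __init__(self, residue: str, position: int, context: str = ""):
        self.residue = residue
        self.position = position
        where = f" in {context}" if context else ""
        super().__init__(
            f"invalid residue {residue!r} at position {position}{where}; "
            "only the 20 natural amino acids (one-letter codes) are allowed"
        )


class EmptySequenceError(CppredError):
    """Sequence is empty after whitespace stripping."""


class EmptyDatasetError(CppredError):
    """Operation requires a non-empty dataset."""


class WindowTooLongError(CppredError):
    """Requested terminal window exceeds the sequence length."""


class SequenceTooShortError(CppredError):
    """Sequence too short for the requested encoding."""


class SchemeMismatchError(CppredError):
    """Feature vector scheme does not match the model's scheme."""


class SingleClassError(CppredError):
    """Both classes must be present."""


class DegenerateFeatureError(CppredError):
    """Feature matrix carries no variance at all."""


class TooFewExamplesError(CppredError):
    """Not enough examples per class for the requested fold count."""


class UndefinedMetricError(CppredError):
    """Metric denominator is zero."""


class FormatError(CppredError):
    """Malformed motif file; message carries the line number."""


class AlphabetError(CppredError):
    """Motif file is not over the protein alphabet."""


class LengthMismatchError(CppredError):
    """Window length does not equal motif width."""


class MotifLongerThanPeptideError(CppredError):
    """Cannot plant a motif longer than the peptide."""


class ModelFileError(CppredError):
    """Model file is unreadable or from an incompatible version."""
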