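"""Exception hierarchy shared across the package."""


class VoxnatError(Exception):
    """Base class for all package errors."""


class FormatError(VoxnatError):
    """Unreadable or unsupported file content."""


class DegenerateInputError(VoxnatError):
    """Input is constant/zero where a normalization or statistic is undefined."""


class UnvoicedError(VoxnatError):
    """No voiced frames were found where periodicity is required."""


class EstimationError(VoxnatError):
    """A required acoustic estimate (e.g. formants) could not be obtained."""


class MissingHarmonicError(VoxnatError):
    """No spectral peak found near the expected harmonic frequency."""


class InsufficientSyllablesError(VoxnatError):
    """Stress contrasts need at least one stressed and one unstressed syllable."""


class ConfigurationError(VoxnatError):
    """Invalid level/emotion/parameter combination."""


class ConstraintError(VoxnatError):
    """An edit would violate a structural constraint (e.g. formant ordering)."""


class LengthError(VoxnatError):
    """A segment is too short for the requested operation."""


class InsufficientDataError(VoxnatError):
    """Not enough samples/trials/channels for the statistic."""


class DesignError(VoxnatError):
    """Malformed statistical design (missing cells, length mismatch...)."""


class DataError(VoxnatError):
    """Invalid labels or values in tabular input."""
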