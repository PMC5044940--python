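"""Exception hierarchy for input validation and pipeline errors."""


class CaseloadError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CaseloadError):
    """Input table does not match the documented column contract."""


class IntegrityError(CaseloadError):
    """Duplicate identifiers or other within-table consistency violations."""


class VocabularyError(CaseloadError):
    """A label is not part of its controlled vocabulary."""


class RowParseError(CaseloadError):
    """A cell could not be parsed; carries the offending row index."""


class ReferentialError(CaseloadError):
    """A cross-table reference does not resolve."""


class InvalidUseError(CaseloadError):
    """A crop or pest label is empty after normalization."""


class ConfigError(CaseloadError):
    """Invalid classifier or scenario configuration."""


class UnassessedSubstanceError(CaseloadError):
    """A product references a substance with no CFS assessment."""


class UndefinedPercentageError(CaseloadError):
    """Percentage requested with a zero denominator."""
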