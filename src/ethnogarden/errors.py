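"""Exception hierarchy for the ethnogarden toolkit."""


class EthnogardenError(Exception):
    """Base class for all package errors."""


class SchemaError(EthnogardenError):
    """A file is structurally malformed: missing column, duplicate header, bad dialect."""


class RecordValidationError(EthnogardenError):
    """One or more records violated domain invariants.

    Carries the :class:`~ethnogarden.inventory.ValidationReport` that lists
    every offending (row, field, message) triple.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class SpeciesNotFoundError(EthnogardenError, KeyError):
    """A species label was not present in the inventory or citation matrix."""


class ScoringError(EthnogardenError):
    """An index could not be computed because required values are absent."""


class InternalConsistencyError(EthnogardenError):
    """A computed quantity fell outside its mathematically guaranteed range."""
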