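"""Exception hierarchy shared across the pipeline."""


class TargetTriageError(Exception):
    """Base class for all package errors."""


class FormatError(TargetTriageError):
    """A file could not be parsed as the expected format."""


class ValidationError(TargetTriageError):
    """Parsed data violate a type invariant."""


class DomainError(TargetTriageError):
    """An operation was called with arguments outside its domain."""


class InsufficientReplicationError(DomainError):
    """A statistical test requires more replicates than were provided."""
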