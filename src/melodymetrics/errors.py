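"""Exception hierarchy for melodymetrics."""


class MelodyMetricsError(Exception):
    """Base class for all package errors."""


class MidiFormatError(MelodyMetricsError):
    """The file is not a parseable Standard MIDI File."""


class EmptyPerformanceError(MelodyMetricsError):
    """A performance contains no notes where at least one is required."""


class InsufficientDataError(MelodyMetricsError):
    """Too few notes (or draws) for the requested computation."""


class DomainError(MelodyMetricsError):
    """An argument lies outside its documented domain."""


class DegenerateColumnError(MelodyMetricsError):
    """A score column is constant where variation is required."""
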