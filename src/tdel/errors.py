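"""Exception hierarchy for the tdel package."""


class TDELError(Exception):
    """Base class for all tdel-specific errors."""


class DesignError(TDELError):
    """An encoding design is infeasible or a bounded search failed."""


class ConfigError(TDELError):
    """A run configuration or input table is invalid."""


class MassUnavailableError(TDELError):
    """A combined mass was requested but a building-block mass is missing."""


class FastqFormatError(TDELError):
    """A FASTQ stream is malformed; carries the 1-based record number."""

    def __init__(self, message: str, record_number: int | None = None):
        super().__init__(message)
        self.record_number = record_number
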