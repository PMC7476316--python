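"""Exception hierarchy for the resin-duct chronology pipeline.

Every error raised deliberately by this package derives from
:class:`DuctChronError`, so callers (and the CLI) can catch one type.
"""


class DuctChronError(Exception):
    """Base class for all ductchron errors."""


class RWLParseError(DuctChronError):
    """A Tucson RWL file violates the decadal layout (names the line number)."""


class MeasurementFormatError(DuctChronError):
    """An ImageJ measurement export is malformed (missing Area column,
    negative area, unterminated final ring, ...)."""


class CoverageError(DuctChronError):
    """A requested year range is not fully covered by a ring-width series."""


class GroupingError(DuctChronError):
    """Cores offered for combination do not belong to one tree."""


class ContractError(DuctChronError):
    """The sample-ID naming contract between duct files and RWL series
    is broken."""


class ValidationError(DuctChronError):
    """Invalid user parameters (simulation settings, config values, ...)."""
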