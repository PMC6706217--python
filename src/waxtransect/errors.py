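"""Exception hierarchy for the waxtransect package.

All package-specific errors derive from :class:`WaxtransectError`, so callers
can catch one base class at pipeline boundaries while tests discriminate on
the concrete type.
"""


class WaxtransectError(Exception):
    """Base class for all waxtransect errors."""


class FormatError(WaxtransectError):
    """A delimited table is structurally malformed (e.g. a mandatory column
    is missing)."""


class ValidationError(WaxtransectError):
    """A record violates a domain invariant (negative concentration,
    non-positive dry mass, humidity outside 0-100%, duplicate site id...)."""


class QuantificationError(WaxtransectError):
    """Peak-table arithmetic cannot proceed (e.g. internal-standard area
    is not positive)."""


class UndefinedMetricError(WaxtransectError):
    """A chain-length metric is undefined for a profile (zero total
    concentration over the requested window, or C29 + C31 == 0)."""


class InsufficientDataError(WaxtransectError):
    """Fewer observations than a statistical routine requires."""


class UnknownIdentifierError(WaxtransectError):
    """A referenced sample, site, species or response name does not exist."""


class StageError(WaxtransectError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
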