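"""Exception hierarchy.

All dosekit errors derive from :class:`DosekitError` so callers can catch
one base class; subclasses distinguish bad numeric input, inconsistent
configuration, malformed study specifications, and fit pathologies.
"""


class DosekitError(Exception):
    """Base class for all dosekit errors."""


class InvalidInputError(DosekitError, ValueError):
    """A numeric argument violates a precondition (e.g. non-positive half-life)."""


class ConfigurationError(DosekitError):
    """Inconsistent or incomplete configuration (units, missing durations...)."""


class SpecificationError(DosekitError):
    """A study or phantom specification is malformed (e.g. overlapping organs)."""


class InsufficientDataError(DosekitError):
    """Too few samples for the requested operation."""


class IntegrabilityError(DosekitError):
    """A fitted curve has no finite integral on (0, inf)."""


class NormalizationError(DosekitError):
    """A kernel deposition profile cannot be normalized to the available energy."""


class TableLookupError(DosekitError, KeyError):
    """A required table entry (S value, organ catalogue) is missing."""
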