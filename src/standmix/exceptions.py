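"""Exception hierarchy shared across standmix modules."""


class StandmixError(Exception):
    """Base class for all standmix errors."""


class DesignError(StandmixError, ValueError):
    """A study design violates its structural invariants."""


class SchemaError(StandmixError, ValueError):
    """A CSV input does not conform to the documented dataset schema."""


class DomainError(StandmixError, ValueError):
    """A metric received an input outside its physical domain."""


class MissingCellError(StandmixError, KeyError):
    """A species x stand cell requested downstream has no observations."""


class IncompleteDesignError(StandmixError, ValueError):
    """A factorial analysis was requested on a layout with empty cells."""


class DegenerateVarianceError(StandmixError, ValueError):
    """A test statistic is undefined because all variability collapsed."""
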