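"""Exception hierarchy used across the package.

All errors derive from :class:`ElevdivError` so callers can catch the
package's failures with a single ``except`` clause while still
distinguishing schema problems from statistical preconditions.
"""


class ElevdivError(Exception):
    """Base class for all errors raised by elevdiv."""


class SchemaError(ElevdivError, ValueError):
    """An input table is missing a mandatory column or has a bad dtype."""


class ValidationError(ElevdivError, ValueError):
    """A field value violates its documented invariant (e.g. elevation <= 0)."""


class ConsistencyError(ElevdivError, ValueError):
    """Two parts of a dataset contradict each other (e.g. captures without effort)."""


class EmptyDatasetError(ElevdivError, ValueError):
    """An operation that needs at least one record received none."""


class UnsupportedInputError(ElevdivError, ValueError):
    """The input lacks information the operation requires (e.g. capture days)."""


class UndefinedIndexError(ElevdivError, ValueError):
    """A diversity index is undefined for this community (e.g. empty)."""


class UndefinedEvennessError(UndefinedIndexError):
    """Pielou's evenness is undefined for communities with fewer than 2 species."""


class ParameterError(ElevdivError, ValueError):
    """A configuration parameter is out of its legal range."""


class MappingError(ElevdivError, ValueError):
    """A site elevation cannot be mapped into the elevational domain."""


class InfeasiblePlacementError(ElevdivError, ValueError):
    """A species range cannot be placed inside the domain under hard boundaries."""


class InfeasibleTestError(ElevdivError, ValueError):
    """A resampling test cannot be run (e.g. null subset smaller than 2 species)."""
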