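"""Exception hierarchy for tracer-accounting and community statistics.

Every precondition violation raises a named subclass of :class:`MycotraceError`
so callers (and the CLI exit-code mapping) can distinguish validation problems
from unmet statistical preconditions.
"""


class MycotraceError(Exception):
    """Base class for all package errors."""


class InvalidIsotopeValueError(MycotraceError, ValueError):
    """An isotope value is outside its physical domain (delta <= -1000 permil
    or atom fraction outside [0, 1])."""


class InvalidSampleError(MycotraceError, ValueError):
    """A sample carries impossible masses (non-positive dry mass, negative
    biomass, element mass exceeding dry mass)."""


class UndefinedRateError(MycotraceError, ZeroDivisionError):
    """A census rate has an empty denominator (no vital tips / no counted
    tips)."""


class InconsistentCensusError(MycotraceError, ValueError):
    """Morphotype counts exceed the vital mycorrhizal tips of the matching
    census row."""


class InconsistentAreasError(MycotraceError, ValueError):
    """Fungal cross-section area exceeds the total cross-section area."""


class UndefinedSimilarityError(MycotraceError, ValueError):
    """Bray-Curtis is undefined because both abundance rows are all zero."""


class DegenerateGroupError(MycotraceError, ValueError):
    """A grouping has fewer groups or fewer members per group than the test
    requires."""


class InconsistentCommunityError(MycotraceError, ValueError):
    """Relative abundances sum to more than one."""


class UndefinedShareError(MycotraceError, ZeroDivisionError):
    """A pool share is requested against a non-positive whole."""


class UndefinedRatioError(MycotraceError, ZeroDivisionError):
    """A transfer ratio is requested with zero heavy nitrogen."""


class DegenerateDesignError(MycotraceError, ValueError):
    """A regression design is degenerate (constant x or n too small)."""


class ThresholdUndefinedError(MycotraceError, ValueError):
    """The x-intercept threshold is requested for a slope that is not
    significantly different from zero."""


class UndefinedCorrelationError(MycotraceError, ValueError):
    """Correlation requested on a constant input."""


class UnbalancedDesignError(MycotraceError, ValueError):
    """A two-way design has empty cells beyond tolerance."""


class SchemaError(MycotraceError, ValueError):
    """An input table violates the expected schema (missing column, bad
    dialect, referential-integrity breach). Carries row context when known."""


class MissingControlsError(MycotraceError, ValueError):
    """Atom-percent excess cannot be computed because a compartment/isotope
    combination has no non-labelled control measurements."""
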