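"""Exception hierarchy.

All frictouch errors derive from :class:`FrictouchError` so callers can
catch the package's failures with a single ``except`` clause.
"""


class FrictouchError(Exception):
    """Base class for all frictouch errors."""


class ParameterError(FrictouchError, ValueError):
    """A model or analysis parameter violates its physical constraints."""


class DomainError(FrictouchError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class IntegrationError(FrictouchError, ArithmeticError):
    """The time integrator produced non-finite forces or positions."""


class DegenerateGeometryError(FrictouchError, ValueError):
    """Scattered points are collinear or otherwise span no area."""


class InsufficientSupportError(FrictouchError, ValueError):
    """A masked grid has too few cells to estimate derivatives."""


class DegenerateHistogramError(FrictouchError, ValueError):
    """An image has a single intensity level; no threshold separates it."""


class FeaturePoorInputError(FrictouchError, ValueError):
    """No trackable features were detected in the first frame."""


class DataError(FrictouchError, ValueError):
    """A response table or trial record is malformed."""


class UndefinedCorrelationError(FrictouchError, ValueError):
    """A rank correlation is undefined (constant input vector)."""
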