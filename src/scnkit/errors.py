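"""Exception hierarchy for the SCN pipeline.

Every error raised by scnkit derives from :class:`SCNError`, so callers can
catch pipeline failures without catching programming errors.
"""


class SCNError(Exception):
    """Base class for all scnkit errors."""


class SchemaError(SCNError):
    """A required column is missing or the column mapping is invalid."""


class CohortValidationError(SCNError):
    """A cohort table violates an input invariant (NaN, non-positive volume...)."""


class SingularDesignError(SCNError):
    """The regression design matrix is rank deficient within the fitting scope."""


class InsufficientDataError(SCNError):
    """Fewer subjects than regression parameters within the fitting scope."""


class DegenerateRegionError(SCNError):
    """A region has zero variance within a group, so Pearson r is undefined."""


class InfeasibleDensityError(SCNError):
    """Requested density needs more edges than there are positive correlations."""

    def __init__(self, msg: str, max_density: float | None = None):
        super().__init__(msg)
        self.max_density = max_density


class NoFeasibleDensityError(SCNError):
    """No grid density up to the cap yields isolated-node-free graphs in both groups."""


class UndefinedMetricsError(SCNError):
    """Graph metrics requested on an empty graph."""


class NormalizationDegenerateError(SCNError):
    """A random-reference mean metric is zero; gamma/lambda undefined."""


class EmptyDistributionError(SCNError):
    """Degree distribution requested on a graph whose nodes all have degree 0."""


class InsufficientSupportError(SCNError):
    """Too few distinct degree values to fit the truncated power law."""


class FitFailureError(SCNError):
    """Degree-distribution fit failed to converge from every starting point."""


class ParameterError(SCNError):
    """An operation received an invalid parameter value."""


class SyntheticSpecError(SCNError):
    """A synthetic cohort specification violates its invariants."""
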