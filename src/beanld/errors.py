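"""Exception hierarchy for the beanld pipeline.

Validation errors signal malformed inputs; computation errors signal
degenerate data (monomorphic loci, singular kinship, empty contingency
margins) that a caller may want to handle per locus pair rather than
abort on.
"""


class BeanLDError(Exception):
    """Base class for all beanld errors."""


class ValidationError(BeanLDError):
    """Input violates a documented precondition or invariant."""


class FormatError(BeanLDError):
    """A file does not conform to the expected dialect."""


class MonomorphicLocusError(BeanLDError):
    """A locus (or a residualized locus) has zero variance."""


class InsufficientDataError(BeanLDError):
    """Too few complete observations to compute a statistic."""


class DegenerateKinshipError(BeanLDError):
    """All lines are identical: the rescaled kinship is undefined."""


class ConditioningError(BeanLDError):
    """Kinship matrix is not positive definite even after ridge."""


class DegenerateTableError(BeanLDError):
    """A 2x2 allele-count table has an empty margin."""


class UnidentifiableFitError(BeanLDError):
    """Decay-curve fit has no information (e.g. a single distance)."""


class UndefinedCorrelationError(BeanLDError):
    """Correlation requested between zero-variance vectors."""


class IncompleteInputError(BeanLDError):
    """A pairwise result required for a map/heatmap is missing."""
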