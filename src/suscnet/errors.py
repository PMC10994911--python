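"""Exception hierarchy shared across the package."""


class SuscnetError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(SuscnetError):
    """Companion volumes do not share a grid shape."""


class FormatError(SuscnetError):
    """A file violates its documented format (e.g. non-integer atlas labels)."""


class CatalogError(SuscnetError):
    """A region id appears in a volume or edge list but not in the region table."""


class CompletenessError(SuscnetError):
    """A subject is missing a region that other subjects have."""


class InsufficientSampleError(SuscnetError):
    """Fewer values than the minimum required for density estimation."""


class DegenerateDistributionError(SuscnetError):
    """A region has zero spread and the degenerate policy is 'error'."""


class EmptyNetworkError(SuscnetError):
    """A sparsity threshold retains zero edges."""


class UndefinedMetricError(SuscnetError):
    """A graph metric is undefined for the given graph (empty, too small)."""


class SurrogateError(SuscnetError):
    """Degree-preserving rewiring failed."""


class AlignmentError(SuscnetError):
    """Subjects or region sets do not line up across inputs."""


class CollinearityError(SuscnetError):
    """A statistical design matrix is rank deficient."""


class ModelError(SuscnetError):
    """A statistical model cannot be fit (degenerate variance, too few rows)."""


class ParameterError(SuscnetError):
    """A configuration parameter is outside its valid range."""


class SpecError(SuscnetError):
    """A synthetic-cohort specification is internally inconsistent."""
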