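"""Exception hierarchy for the dcar package."""


class DcarError(Exception):
    """Base class for all dcar errors."""


class SchemaError(DcarError):
    """An input table violates the documented column/value schema."""


class CoverageError(DcarError):
    """A requested time window extends beyond the available series coverage."""


class MissingDataError(DcarError):
    """No usable observations inside a requested window."""


class DataIntegrityError(DcarError):
    """Internally inconsistent records (e.g. a pregnancy ending before conception)."""


class InsufficientClustersError(DcarError):
    """Cluster-robust inference requires at least two clusters."""


class NotEstimableError(DcarError):
    """A requested quantity is absorbed by the fixed-effect specification."""


class NotTestableError(DcarError):
    """The data cannot identify the requested test (e.g. one-signed deltas)."""


class DegenerateVarianceError(DcarError):
    """A test statistic has zero variance but a nonzero estimate."""
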