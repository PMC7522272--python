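"""Exception hierarchy shared by all pipeline stages."""


class OPWFError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(OPWFError, ValueError):
    """A pulse-template specification violates its invariants."""


class InvalidConfigError(OPWFError, ValueError):
    """A study or pipeline configuration violates its invariants."""


class BoundsError(OPWFError, IndexError):
    """An ROI rectangle does not fit inside the frame."""


class DegenerateSegmentationError(OPWFError, ValueError):
    """No threshold separates vessel from tissue (e.g. constant map, empty mask)."""


class SynchronizationError(OPWFError, ValueError):
    """No cardiac periodicity detectable in a region-mean series."""


class DegeneratePhaseError(OPWFError, ValueError):
    """Waveform peak lies on the cycle boundary; rise/fall phases undefined."""


class DomainError(OPWFError, ValueError):
    """Arithmetic precondition violated (e.g. DC <= 0 in the blowout score)."""


class UnderdeterminedFitError(OPWFError, ValueError):
    """Fewer than three distinct time points for the quadratic fit."""


class NormalizationError(OPWFError, ValueError):
    """Baseline mean missing, zero or negative during baseline normalization."""


class DegenerateTestError(OPWFError, ValueError):
    """Repeated-measures test with zero within-subject variance everywhere."""


class UndefinedCorrelationError(OPWFError, ValueError):
    """Correlation requested on a constant margin."""


class CollinearityError(OPWFError, ValueError):
    """Rank-deficient design matrix in the multivariate regression."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear or constant columns: {self.columns}")


class MissingTrendError(OPWFError, KeyError):
    """Phase classification called without all six parameter trends."""


class ValidationError(OPWFError, ValueError):
    """An NBA record has out-of-range items."""


class SchemaError(OPWFError, ValueError):
    """A CSV dataset does not match the expected schema."""
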