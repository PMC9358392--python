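"""Exception hierarchy shared across the package."""


class XenospotError(Exception):
    """Base class for all package-specific errors."""


class MalformedRecordError(XenospotError):
    """An alignment record violates its invariants (next > best, length <= 0)."""


class FormatError(XenospotError):
    """An input file violates its format contract (unsorted SAM, bad BED line)."""


class UndefinedXtfError(XenospotError):
    """xTF denominator is zero: no species-specific fragments above threshold."""


class EmptyDistributionError(XenospotError):
    """No fragments of the requested category."""


class NormalisationError(XenospotError):
    """Baseline xTF missing or zero; the series cannot be normalised."""


class InsufficientPoolError(XenospotError):
    """A dilution pool is smaller than the design requires."""


class CoordinateError(XenospotError):
    """A fragment lies beyond the end of its chromosome."""


class CorrectionError(XenospotError):
    """Bias correction impossible (e.g. no usable bins)."""


class FitError(XenospotError):
    """Model fitting failed or was attempted on degenerate input."""


class RankError(FitError):
    """Design matrix is rank deficient / parameters not identifiable."""


class CoverageError(XenospotError):
    """A queried region is not covered by any copy-number segment."""


class GridError(XenospotError):
    """A search grid is empty or degenerate."""


class ConfigError(XenospotError):
    """Study configuration failed validation."""
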