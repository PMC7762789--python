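"""Exception types shared across the pipeline stages."""


class ExoReleaseError(Exception):
    """Base class for all pipeline errors."""


class InfeasibleConfigError(ExoReleaseError):
    """A simulation configuration cannot produce the promised ground truth."""


class DuplicateIdError(ExoReleaseError):
    """A feature or gene id occurs more than once in an input table."""


class ParseError(ExoReleaseError):
    """A cell in an input table could not be interpreted."""


class UnknownSampleError(ExoReleaseError):
    """A sample id referenced by the caller is absent from the metadata."""


class MissingControlsError(ExoReleaseError):
    """The release filter needs external-control samples and found none."""


class MissingTimepointError(ExoReleaseError):
    """A required time point (e.g. the 45 h endpoint) has no samples."""


class NoValidItsdError(ExoReleaseError):
    """No internal-standard candidate is nonzero in every sample."""


class InvalidReferenceError(ExoReleaseError):
    """The chosen reference feature is zero in at least one sample."""


class NegativeAbundanceError(ExoReleaseError):
    """Bray-Curtis dissimilarity requires nonnegative profiles."""


class DegenerateFactorError(ExoReleaseError):
    """A PERMANOVA/ANOVA factor has fewer than two usable levels."""


class UnbalancedSeriesError(ExoReleaseError):
    """Repeated-measures permutations need each series to cover every time point once."""


class DegenerateConfigurationError(ExoReleaseError):
    """A Procrustes input configuration is rank-deficient."""


class EmptyGroupError(ExoReleaseError):
    """A centroid was requested for a group with no samples."""
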