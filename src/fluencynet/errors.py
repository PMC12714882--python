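"""Exception hierarchy for the fluency-network pipeline.

Every stage raises a subclass of :class:`FluencyNetError`, so callers can
catch pipeline failures without masking programming errors.
"""


class FluencyNetError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FluencyNetError):
    """Malformed input configuration (missing columns, bad dialect, bad params)."""


class EmptyDatasetError(FluencyNetError):
    """An input file or dataset contains no participant records."""


class EmptyMatrixError(FluencyNetError):
    """Filtering removed every word column from a response matrix."""


class EmptySharedLexiconError(FluencyNetError):
    """Node equating found no words shared between the two groups."""


class SingularDesignError(FluencyNetError):
    """A regression design matrix is rank deficient."""


class TooFewNodesError(FluencyNetError):
    """A graph operation needs more nodes than the input provides."""


class UndefinedMetricError(FluencyNetError):
    """A graph metric is undefined for this input (e.g. ASPL of an edgeless graph)."""


class DegenerateDistributionError(FluencyNetError):
    """A reference distribution has zero spread, so a z- or t-test is undefined."""
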