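"""Exception hierarchy shared across the pipeline stages."""


class ThyroclassError(Exception):
    """Base class for all package errors."""


class ConfigError(ThyroclassError):
    """Invalid configuration (non-positive dimensions, unknown modes, ...)."""


class ValidationError(ThyroclassError):
    """Malformed input records or matrices (missing fields, out-of-range values)."""


class NormalizationError(ThyroclassError):
    """Size-factor estimation failed (e.g. no gene expressed in every sample)."""


class UnresolvedClusterError(ThyroclassError):
    """A cluster cannot be typed as BRAF-like or RAS-like.

    Raised when a cluster contains no driver-positive sample, or its
    driver-positive samples tie between BRAF-type and RAS-type, so the
    driver-negative samples inside it cannot inherit a class. Carries the
    affected negative sample ids in ``negatives``.
    """

    def __init__(self, message: str, negatives: list[str] | None = None):
        super().__init__(message)
        self.negatives = list(negatives or [])
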