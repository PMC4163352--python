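"""Exception hierarchy shared across the package.

All validation failures derive from :class:`SmoothcastError` so the CLI can
map them onto stable exit codes (config errors -> 2, data errors -> 3).
"""


class SmoothcastError(Exception):
    """Base class for all package errors."""


class ConfigError(SmoothcastError):
    """Invalid configuration (unknown model id, bad hyperparameter, ...)."""


class DataError(SmoothcastError):
    """Invalid input data (non-finite values, unreadable file, ...)."""


class LengthError(DataError):
    """A series is too short for the requested operation."""


class DimensionError(DataError):
    """Incompatible array dimensions (Hankel order, regressor width, ...)."""


class ScalingError(DataError):
    """Degenerate series cannot be min-max scaled."""


class SplitError(DataError):
    """A train/test split would leave a partition empty."""


class FitError(SmoothcastError):
    """Model estimation failed (non-convergence, divergent fitness)."""


class UndefinedMetricError(SmoothcastError):
    """A metric is undefined for the given inputs (e.g. zero observations)."""

    def __init__(self, message: str, indices=None):
        super().__init__(message)
        self.indices = list(indices) if indices is not None else []
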