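"""Exception hierarchy.

Validation problems (bad tables, bad configuration) and numerical problems
(degenerate samples, non-convergence) are kept distinct so the CLI can map
them to different exit codes.
"""


class AsymreproError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AsymreproError, ValueError):
    """Invalid simulation or run configuration."""


class SchemaError(AsymreproError, ValueError):
    """An input table violates the summary-statistics schema."""


class DegenerateSampleError(AsymreproError, ValueError):
    """A sample admits no test statistic (e.g. zero variance of differences)."""


class ConvergenceError(AsymreproError, RuntimeError):
    """An iterative estimator failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_value: float | None = None):
        super().__init__(message)
        self.last_value = last_value
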