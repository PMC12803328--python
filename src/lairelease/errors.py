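"""Exception hierarchy for the package.

Every error raised deliberately by the library derives from
:class:`LaiReleaseError`, so callers (and the CLI) can distinguish user /
data problems from genuine bugs.
"""


class LaiReleaseError(Exception):
    """Base class for all package errors."""


class DegenerateProfileError(LaiReleaseError):
    """A release profile cannot be normalized (too few points, zero time
    range, or all-zero release under max-normalization)."""


class OutOfBracketError(LaiReleaseError):
    """Interpolation was requested outside the bracketing knots."""


class InsufficientDurationError(LaiReleaseError):
    """A profile ends before the requested early time point."""


class InvalidDescriptorError(LaiReleaseError):
    """A shape descriptor (e.g. AUC) is negative or non-finite."""


class ConfigError(LaiReleaseError):
    """A configuration value is outside its allowed space."""


class SchemaError(LaiReleaseError):
    """An input file or run configuration does not match the schema."""


class CrossReferenceError(LaiReleaseError):
    """Profiles and formulation records do not refer to the same ids."""


class ShapeError(LaiReleaseError):
    """Array arguments have incompatible shapes."""


class DegenerateTrainingError(LaiReleaseError):
    """Training data is degenerate (e.g. a single class for a classifier)."""


class DivergenceError(LaiReleaseError):
    """Model training produced a non-finite loss."""


class UndefinedCorrelationError(LaiReleaseError):
    """Pearson correlation is undefined (zero variance input)."""


class UnsupportedExplainerError(LaiReleaseError):
    """No exact Shapley explainer is available for this model family."""
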