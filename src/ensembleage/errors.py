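"""Exception hierarchy shared across the package.

All errors raised on purpose derive from :class:`EnsembleAgeError` so callers
(and the command-line layer) can distinguish anticipated failures from bugs.
"""


class EnsembleAgeError(Exception):
    """Base class for all anticipated errors."""


class FormatError(EnsembleAgeError):
    """A file does not follow the expected tabular layout."""


class ValidationError(EnsembleAgeError):
    """Parsed content violates a domain invariant (range, uniqueness, ...)."""


class CoverageError(EnsembleAgeError):
    """Too many of a clock's CpGs are absent from the input matrix."""


class ConsistencyError(EnsembleAgeError):
    """Clock coefficient table and metadata sidecar disagree."""


class DesignError(EnsembleAgeError):
    """A regression design is degenerate (constant predictor, too few rows)."""


class RecipeError(EnsembleAgeError):
    """A clock recipe cannot be realized (e.g. pre-selection is empty)."""


class LibraryError(EnsembleAgeError):
    """Every recipe in a clock-library grid failed."""


class StratumError(EnsembleAgeError):
    """A stratum lacks the samples required by a benchmark operation."""


class SplitError(EnsembleAgeError):
    """A requested train/test or panel split is impossible."""


class SelectionError(EnsembleAgeError):
    """Ensemble selection was asked for more clocks than were scored."""


class CalibrationError(EnsembleAgeError):
    """Age calibration was requested in a setting where it is undefined."""


class TrainingError(EnsembleAgeError):
    """Not enough samples to train a model."""


class ConfigError(EnsembleAgeError):
    """Run configuration contains unknown keys or out-of-domain values."""
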