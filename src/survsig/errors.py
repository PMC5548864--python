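"""Exception hierarchy for survsig.

Everything raised on purpose derives from :class:`SurvsigError`, so callers
can catch one base class at the CLI boundary.
"""


class SurvsigError(Exception):
    """Base class for all survsig errors."""


class ParseError(SurvsigError):
    """A TSV input file violates the expected schema; the message names the offending line/column."""


class EmptyJoinError(SurvsigError):
    """Expression and clinical tables share no patient identifiers."""


class InsufficientCohortError(SurvsigError):
    """A cohort is too small for the requested operation (e.g. fewer samples than CV folds)."""


class UndefinedCorrelationError(SurvsigError):
    """Pearson correlation requested on a constant vector."""


class FitError(SurvsigError):
    """The SVR solver failed; carries the hyperparameters that triggered it."""


class ConfigError(SurvsigError):
    """Invalid configuration value (GA settings, grids, simulation spec)."""


class SchemaError(SurvsigError):
    """Mismatched shapes or feature sets between two objects that must agree."""
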