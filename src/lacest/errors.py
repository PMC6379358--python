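"""Exception hierarchy.

All package-specific failures derive from :class:`LacestError` so callers
(and the CLI) can distinguish data/model problems from genuine bugs or
ordinary I/O failures.
"""


class LacestError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(LacestError):
    """A CSV file is missing a required column or has a malformed header."""


class ValidationError(LacestError):
    """A record violates a documented invariant (names row and rule)."""


class LinkageError(LacestError):
    """A test record references a subject_id that does not resolve."""


class SpecError(LacestError):
    """A feature specification names an unknown/duplicated variable, or a
    dataset lacks a variable the model was trained with."""


class DegenerateFeatureError(LacestError):
    """A variable is constant on the training data and cannot be z-scored."""


class FitError(LacestError):
    """A least-squares fit was requested on empty or unusable input."""


class FoldError(LacestError):
    """Too few observations to run leave-one-out cross-validation."""


class StratificationError(LacestError):
    """A requested intensity stratum contains no test records."""


class ScaleError(LacestError):
    """Weightings were requested from a model fitted on unstandardized
    features; weights are only comparable on a common scale."""


class NormalizationError(LacestError):
    """All candidate weights are zero; normalized weights are undefined."""


class ConfigError(LacestError):
    """A synthetic-cohort configuration is invalid."""
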