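"""Exception hierarchy.

All metamatch errors derive from :class:`MetamatchError` so callers can catch
the whole family; the subclasses distinguish bad inputs, degenerate numerics,
protocol misuse (e.g. too few participants for a 5-fold split) and container
format problems.
"""


class MetamatchError(Exception):
    """Base class for all metamatch errors."""


class ValidationError(MetamatchError, ValueError):
    """Input violates a structural precondition (shape, symmetry, labels)."""


class DegenerateInputError(MetamatchError, ValueError):
    """Input is structurally fine but numerically degenerate (e.g. a
    constant feature vector, for which a correlation is undefined)."""


class ProtocolError(MetamatchError, ValueError):
    """The experimental protocol cannot run as requested (e.g. K-shot with
    fewer observed participants than K, or fewer participants than folds)."""


class ConfigurationError(MetamatchError, ValueError):
    """Inconsistent configuration (e.g. a model grouping with no
    extra-large dataset, or a variant/feature-count mismatch)."""


class NumericalError(MetamatchError, ArithmeticError):
    """A linear solve failed; usually fixable with regularization > 0."""


class StateError(MetamatchError, RuntimeError):
    """An object was used before it was trained/initialized."""


class FileFormatError(MetamatchError, OSError):
    """A container on disk is malformed, truncated, or of the wrong version."""
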