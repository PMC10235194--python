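"""Exception hierarchy for flone.

Every error raised by the package derives from :class:`FloneError`, so callers
can catch package failures with a single ``except`` clause while still getting
the standard-library semantics (``ValueError``, ``KeyError``...) for free.
"""


class FloneError(Exception):
    """Base class for all flone errors."""


class DimensionError(FloneError, ValueError):
    """Vector/matrix shapes are incompatible with the requested operation."""


class GeometryError(FloneError, ValueError):
    """Input violates a Lorentz-manifold precondition (off-manifold point, bad curvature)."""


class DegenerateTransformError(GeometryError):
    """A fully Lorentz linear layer produced a zero spatial image (collapsed weights)."""


class VocabularyError(FloneError, KeyError):
    """An entity id is not present in the model vocabulary."""


class ConfigurationError(FloneError, ValueError):
    """Inconsistent model/training configuration (e.g. encoder variant without features)."""


class CoverageError(FloneError, KeyError):
    """An entity lacks both a trained embedding row and encoder features."""


class SamplingError(FloneError, RuntimeError):
    """No admissible negative target exists for a (drug, disease) query."""


class SplitError(FloneError, ValueError):
    """A data split cannot be constructed (too few drug-target pairs, bad ratios)."""


class EvaluationError(FloneError, ValueError):
    """Ranking evaluation received invalid input (empty result list, missing candidate)."""


class TrainingError(FloneError, RuntimeError):
    """Optimization failed (non-finite gradients, inconsistent state)."""


class ParseError(FloneError, ValueError):
    """A TSV/JSON input file is malformed; carries the offending line number when known."""
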