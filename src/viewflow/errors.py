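"""Exception hierarchy.

Everything raised on bad user input derives from :class:`ViewflowError` so
callers can catch one base class; subclasses distinguish parse problems from
semantic validation and from genuinely degenerate geometry/statistics.
"""


class ViewflowError(Exception):
    """Base class for all errors raised by this package."""


class MeshFormatError(ViewflowError):
    """A mesh file could not be parsed; the message names the offending line."""


class ValidationError(ViewflowError):
    """An input violates a documented precondition or invariant."""


class DegenerateMeshError(ViewflowError):
    """Mesh geometry collapses (all vertices coincident, zero extent)."""


class ProjectionError(ViewflowError):
    """A point cannot be projected (at or behind the perspective camera)."""


class NoOverlapError(ViewflowError):
    """No vertex is visible in both compared poses; the flow mean is undefined."""


class MissingCellError(ViewflowError):
    """A psychometric cell required by an analysis is absent from the table."""


class DegeneratePredictorError(ViewflowError):
    """A regression predictor is constant (or otherwise rank-deficient)."""
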