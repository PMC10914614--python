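"""Exception hierarchy used across the package.

Every error raised by gradscope derives from :class:`GradscopeError`, so
callers can catch one type at a pipeline boundary while tests discriminate
on the specific subclass.
"""


class GradscopeError(Exception):
    """Base class for all gradscope errors."""


class FormatError(GradscopeError):
    """An on-disk table violates the expected dialect (missing column,
    unparseable value, unknown vocabulary term, bad column order)."""


class IntegrityError(GradscopeError):
    """A table parsed but its content is inconsistent (duplicate ids,
    missing spike-in row, negative values)."""


class ParameterError(GradscopeError):
    """A function argument is outside its documented domain."""


class DegenerateSpikeInError(GradscopeError):
    """The spike-in row contains a zero or non-positive value, so
    per-fraction correction factors are undefined."""


class EmptyProfileError(GradscopeError):
    """A protein row is all-zero; no sedimentation profile can be formed."""


class UndefinedCorrelationError(GradscopeError):
    """Pearson correlation requested on a zero-variance fraction vector."""


class InsufficientReferenceError(GradscopeError):
    """A reference-complex label has fewer annotated members than required
    to form a trustworthy centroid."""


class AmbiguousSubunitError(GradscopeError):
    """30S-vs-50S classification is a tie within numerical tolerance; the
    call must be resolved by manual review, never silently."""


class UndefinedFractionError(GradscopeError):
    """A per-time-point read fraction is undefined (zero total counts)."""


class DegenerateCurveError(GradscopeError):
    """A standard curve has non-positive slope; quantitation is impossible."""


class PipelineError(GradscopeError):
    """A pipeline stage failed; the message names the stage and the
    offending record or path."""
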