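"""Exception hierarchy shared across the pipeline stages.

Every stage raises a subclass of :class:`EllipickError` so callers can tag
failures with the stage that produced them.
"""


class EllipickError(Exception):
    """Base class for all package errors."""


class InvalidConicError(EllipickError):
    """The six-coefficient vector does not describe a usable conic."""


class EllipseFitError(EllipickError):
    """Least-squares fit failed: too few points, degenerate configuration,
    or the constrained solution is not an ellipse."""


class DegenerateConicError(EllipickError):
    """Conic is an ellipse by discriminant but degenerates to a point or an
    imaginary locus; no real parametric form exists."""


class EmptyMaskError(EllipickError):
    """A stage that needs foreground pixels received none."""


class SelectionError(EllipickError):
    """No candidate component produced a valid ellipse."""


class ClippingError(EllipickError):
    """A crop box fell entirely outside the image after clipping."""


class ContractViolationError(EllipickError):
    """A pluggable predictor returned an invalid class or confidence."""


class AnnotationError(EllipickError):
    """An annotation file violates the documented schema."""
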