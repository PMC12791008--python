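"""Exception hierarchy for morphaline."""


class MorphalineError(Exception):
    """Base class for all package-specific errors."""


class InvalidGridError(MorphalineError):
    """Grid construction or truncation produced an unusable grid."""


class NoStripeError(MorphalineError):
    """No above-threshold stripe component found in the image."""


class UndefinedCorrelationError(MorphalineError):
    """Correlation is undefined (constant input, or no valid nodes)."""


class DegenerateOverlapError(MorphalineError):
    """Similarity-matrix endpoints do not bound a monotone path."""


class NoPathError(MorphalineError):
    """No finite-cost monotone path between the selected endpoints."""


class AmbiguousLandmarkError(MorphalineError):
    """Landmark-derivative profile has no unique maximum."""


class CannotFuseError(MorphalineError):
    """Recordings cannot be fused into one consensus timeline."""


class UncertaintyUndefinedError(MorphalineError):
    """Chi-squared parabola fit is non-convex; sigma_t undefined."""


class FitError(MorphalineError):
    """A model fit failed to converge or was degenerate."""


class BoundaryTimestampWarning(UserWarning):
    """Chi-squared minimum sits on the boundary of the timeline."""


class TieWarning(UserWarning):
    """A maximization had ties; the documented tie-break was applied."""
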