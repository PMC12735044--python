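"""Exception hierarchy shared across the pipeline.

Two failure classes map onto the CLI exit codes: malformed or inconsistent
input (:class:`ValidationError`, exit 2) and inputs that are well-formed but
make a computation mathematically degenerate (:class:`DegenerateError`,
exit 3).
"""


class LabscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(LabscreenError):
    """Input fails a structural or domain invariant (missing cells,
    duplicate records, non-finite values, unknown indicator, ...)."""


class DegenerateError(LabscreenError):
    """Computation is undefined for this input: zero control absorbance,
    zero-slope standard curve, every indicator column constant, ..."""


class QualityWarning(UserWarning):
    """A value is returned unclamped but is physically suspicious
    (negative concentration, percentage outside [0, 100], entropy-unsafe
    zeros after a zero-epsilon shift)."""
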