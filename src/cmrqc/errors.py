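"""Exception hierarchy for cmrqc.

All library errors derive from :class:`CmrqcError` so callers (and the CLI)
can map validation problems and I/O problems to distinct exit codes.
"""


class CmrqcError(Exception):
    """Base class for all cmrqc errors."""


class ValidationError(CmrqcError, ValueError):
    """Invalid input data or arguments."""


class DegenerateGeometryError(ValidationError):
    """A polygon/ring is degenerate (too few vertices, zero area, self-intersecting)."""


class ContainmentError(ValidationError):
    """Endocardial contour not contained in the epicardial contour beyond tolerance."""


class AlignmentError(ValidationError):
    """Two contour stacks do not share the same slice/phase grid or case pairing."""


class PhaseError(ValidationError):
    """A required cardiac phase (ED/ES) is not annotated."""


class FormatError(ValidationError):
    """A file does not conform to the contour-stack or label-mask format."""


class IOFailure(CmrqcError, OSError):
    """Filesystem-level read/write failure."""
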