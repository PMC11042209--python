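"""Exception hierarchy for reachkin."""


class ReachkinError(Exception):
    """Base class for all reachkin errors."""


class FormatError(ReachkinError):
    """A file is syntactically readable but violates the expected layout
    (e.g. a declared keypoint column is missing)."""


class StructuralError(ReachkinError):
    """Parsed content violates a structural invariant
    (e.g. non-contiguous frame index, decreasing sensor-log frames)."""


class SegmentValidationError(ReachkinError):
    """Manual reach spans are out of range or overlap.

    The offending spans are kept on the ``offenders`` attribute.
    """

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)


class DegenerateGeometryError(ReachkinError):
    """Geometric configuration is degenerate (coplanar calibration points,
    collinear reference points, zero mirror normal, ...)."""


class InsufficientDataError(ReachkinError):
    """Too few data points for the requested estimation."""
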