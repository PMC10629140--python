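"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`SctRadiomicsError`
so callers can catch pipeline failures without swallowing programming errors.
"""


class SctRadiomicsError(Exception):
    """Base class for all package errors."""


class FormatError(SctRadiomicsError):
    """A file could not be parsed as a supported volume format."""


class DimensionalityError(SctRadiomicsError):
    """A volume payload is not three-dimensional."""


class GeometryError(SctRadiomicsError):
    """Grids of paired volumes/masks disagree, or an object cannot fit a grid."""


class EmptyMaskError(SctRadiomicsError):
    """An ROI mask has no foreground voxels."""


class DegenerateRangeError(SctRadiomicsError):
    """An intensity operation requires a non-constant volume."""


class DegenerateTestError(SctRadiomicsError):
    """A statistical test cannot be computed (e.g. zero-variance differences)."""


class AlignmentError(SctRadiomicsError):
    """Paired tables do not share subjects/ROIs/features."""


class InsufficientPointsError(SctRadiomicsError):
    """Too few points for a correlation."""


class LookupError_(SctRadiomicsError):
    """Requested feature names are absent from the feature universe."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"unknown feature names: {', '.join(self.missing)}")
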