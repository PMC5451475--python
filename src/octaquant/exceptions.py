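"""Exception hierarchy for the OCT-A quantification pipeline.

Every contract violation raises a distinct, named error so that batch
drivers can report which stage failed and why.
"""


class OctaError(Exception):
    """Base class for all octaquant errors."""


class ChannelMismatchError(OctaError):
    """Multi-channel image whose channels differ (a true color image)."""


class DimensionMismatchError(OctaError):
    """Pixel dimensions of an image disagree with the declared scan geometry."""


class EmptyRecordsError(OctaError):
    """A metric table writer was given no records."""


class WindowTooLargeError(OctaError):
    """A local filter window does not fit inside the image."""


class SeedSearchError(OctaError):
    """No background pixel found near the requested FAZ seed."""


class EmptyRegionError(OctaError):
    """An operation requiring a non-empty pixel region received an empty one."""


class ZeroPerimeterError(OctaError):
    """Circularity requested for a region with zero perimeter."""


class GridFitError(OctaError):
    """The ETDRS outer circle does not fit inside the scan."""


class ZeroSkeletonError(OctaError):
    """Vessel diameter index requested with zero skeleton length."""


class InsufficientScalesError(OctaError):
    """Too few box sizes available for a box-counting fit."""


class UnbalancedDataError(OctaError):
    """Repeated-measures table is not a complete subjects x sessions grid."""


class DegenerateDataError(OctaError):
    """Repeated-measures table has zero total variance or too few rows."""


class InfeasibleSceneError(OctaError):
    """Synthetic scene parameters describe an impossible scene."""


class StageError(OctaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
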