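"""Exception and warning hierarchy.

Every stage of the pipeline raises a distinct subclass of
:class:`RadialFishError` so that callers (and the CLI) can attribute a
failure to the stage that produced it.
"""


class RadialFishError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RadialFishError):
    """A scene or run configuration is internally inconsistent."""


class SegmentationError(RadialFishError):
    """Nucleus segmentation failed or produced an unusable mask."""


class PartitionError(RadialFishError):
    """The nucleus mask cannot be partitioned into shells."""


class ProfileError(RadialFishError):
    """Per-shell signal measurement is degenerate (no probe / no DAPI)."""


class AggregationError(RadialFishError):
    """A cohort is too small to aggregate or compare."""


class TerritoryDetectionError(RadialFishError):
    """No chromosome-territory component survives segmentation/filtering."""


class GeometryError(RadialFishError):
    """A territory lies in an invalid position relative to the mask."""


class AmbiguousSegmentationWarning(UserWarning):
    """More than one comparably sized DAPI component; the largest was kept."""


class SmallCohortWarning(UserWarning):
    """Cohort smaller than the recommended minimum number of nuclei."""


class TerritoryCountWarning(UserWarning):
    """Detected territory count deviates from the expected count."""
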