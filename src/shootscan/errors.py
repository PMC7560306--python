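"""Exception hierarchy for the shootscan pipeline.

Every failure mode a caller can act on has its own class; all derive from
:class:`ShootScanError` so batch drivers can trap per-image failures without
masking programming errors.
"""


class ShootScanError(Exception):
    """Base class for all shootscan-specific errors."""


class InvalidRectangleError(ShootScanError):
    """Crop rectangle is empty or falls outside the image bounds."""


class ConfigError(ShootScanError):
    """Invalid analysis configuration (e.g. even median kernel)."""


class DegenerateHistogramError(ShootScanError):
    """Automatic thresholding on an image with fewer than two gray levels."""


class BarNotFoundError(ShootScanError):
    """No plausible scale bar in the configured corner window."""


class TooSmallObjectError(ShootScanError):
    """Region too small to yield a usable skeleton."""


class AllPrunedError(ShootScanError):
    """Pruning would leave fewer than two graph nodes."""


class UnreachableNodeError(ShootScanError):
    """Shortest-path source cannot reach every node (disconnected graph)."""


class MeasurementError(ShootScanError):
    """Graph unsuitable for trait measurement (fewer than two nodes)."""


class InsufficientSampleError(ShootScanError):
    """Too few observations for the requested statistic."""


class UnknownRegionError(ShootScanError):
    """A region id was referenced that does not exist."""


class InvalidSceneError(ShootScanError):
    """Synthetic scene specification cannot be rendered (e.g. overlap)."""


class FixtureError(ShootScanError):
    """Rasterized skeleton fixture does not realize its specification."""
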