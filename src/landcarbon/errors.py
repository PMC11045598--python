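"""Exception types shared across the package."""


class LandCarbonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LandCarbonError, ValueError):
    """A scenario or run configuration is invalid."""


class ValidationError(LandCarbonError, ValueError):
    """An input object violates one of its invariants."""


class GridMismatchError(LandCarbonError, ValueError):
    """Two rasters do not share grid shape / class set."""


class SamplingError(LandCarbonError, ValueError):
    """A sampling request cannot be satisfied by the map."""


class AllocationError(LandCarbonError, ValueError):
    """Spatial change allocation demand cannot be met."""
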