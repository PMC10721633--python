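"""Exception types shared across the pipeline."""


class SpotdropError(Exception):
    """Base class for all spotdrop errors."""


class UnsupportedFormatError(SpotdropError):
    """Input file is not a single-channel multipage TIFF."""


class EmptyMovieError(SpotdropError):
    """Movie has zero frames."""


class SchemaError(SpotdropError):
    """A table file is missing a required column."""


class CrowdedFieldError(SpotdropError):
    """Spot placement failed: the field cannot hold the requested spots
    at the requested minimum spacing."""


class ConstantImageError(SpotdropError):
    """Shift estimation is undefined for a constant image."""


class GridMismatchError(SpotdropError):
    """Plate wells do not share a common timepoint grid."""


class NoTransitionError(SpotdropError):
    """Melt curve shows no detectable transition."""
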