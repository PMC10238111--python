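"""Exception hierarchy.

All domain errors derive from :class:`RicePamError` so callers can catch one
base class; each subclass corresponds to a distinct failure mode of the
pipeline (bad spectra, degenerate fits, misaligned rasters, ...).
"""


class RicePamError(ValueError):
    """Base class for all ricepam domain errors."""


class MissingBandError(RicePamError):
    """A vegetation-index formula needs a band the sample does not carry."""

    def __init__(self, band_nm: int, vi_name: str = ""):
        self.band_nm = band_nm
        self.vi_name = vi_name
        suffix = f" (required by {vi_name})" if vi_name else ""
        super().__init__(f"missing band: {band_nm} nm{suffix}")


class DegenerateReflectanceError(RicePamError):
    """A vegetation-index denominator vanished; no finite value exists."""


class DegeneratePanelError(RicePamError):
    """All calibration-panel digital numbers coincide; no line can be fit."""


class GridMismatchError(RicePamError):
    """Two rasters that must share geometry do not."""


class EmptyROIError(RicePamError):
    """A plot polygon covers no valid raster cells."""


class DegenerateDesignError(RicePamError):
    """The regressor is constant (or there are too few points) for OLS."""


class NonMonotoneTrajectoryError(RicePamError):
    """Trajectory observation times are not strictly increasing."""


class ConstantResponseError(RicePamError):
    """Measured response has zero variance; R-squared is undefined."""
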