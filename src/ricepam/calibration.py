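"""Radiometric calibration, canopy height from DSM differencing, zonal stats.

The empirical line method converts camera digital numbers (DN) to surface
reflectance with a per-band linear model ``R = gain * DN + offset`` fitted
by ordinary least squares on ground calibration panels of known
reflectance (the standard ladder is 0.03, 0.06, 0.12, 0.24, 0.36, 0.48,
0.56, 0.80).

Canopy height comes from differencing a crop-season digital surface model
against the bare-soil DSM acquired before transplanting::

    H = DSM - DSM_soil

Plot-level means are extracted with a cell-center-in-polygon rule over
GeoJSON regions of interest.

Rasters are plain numpy grids wrapped in :class:`Raster` (row-major,
origin at the top-left corner, square-cell north-up georeferencing, an
explicit nodata sentinel, and a CRS tag compared as an opaque string).
Text I/O uses the ESRI ASCII grid format.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegeneratePanelError,
    EmptyROIError,
    GridMismatchError,
    RicePamError,
)

logger = logging.getLogger(__name__)

#: Known reflectances of the standard 8-panel calibration ladder.
DEFAULT_PANEL_LADDER = (0.03, 0.06, 0.12, 0.24, 0.36, 0.48, 0.56, 0.80)

#: Reflectance values outside this interval are clipped (not [0, 1]: we keep
#: moderate overshoot visible so calibration problems are not hidden).
REFLECTANCE_CLIP = (0.0, 1.5)


# ---------------------------------------------------------------------------
# Raster container
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """A georeferenced single-band grid.

    ``data`` is row-major with row 0 at the top; ``origin`` is the (x, y)
    of the top-left corner; ``cellsize`` is the square cell edge in CRS
    units.  ``nodata`` cells are stored as the sentinel value itself.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cellsize: float = 1.0
    crs: str = "local"
    nodata: float = -9999.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RicePamError(f"raster data must be 2-D, got shape {self.data.shape}")

    @property
    def geometry(self) -> tuple:
        return (self.data.shape, self.origin, self.cellsize, self.crs)

    def mask(self) -> np.ndarray:
        """Boolean mask, True where the cell is valid (not nodata, not NaN)."""
        return np.isfinite(self.data) & (self.data != self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of every cell center."""
        nrow, ncol = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cellsize
        ys = y0 - (np.arange(nrow) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and self.origin == other.origin
            and self.cellsize == other.cellsize
            and self.crs == other.crs
        )


def require_aligned(a: Raster, b: Raster) -> None:
    if not a.aligned_with(b):
        raise GridMismatchError(
            f"grid mismatch: {a.geometry} vs {b.geometry}"
        )


def read_ascii_grid(path, crs: str = "local") -> Raster:
    """Read an ESRI ASCII grid (.asc) file."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RicePamError(f"ASCII grid missing header key: {key}")
    data = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise RicePamError(
            f"ASCII grid body shape {data.shape} != header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Raster(data, origin=origin, cellsize=cell, crs=crs,
                  nodata=header.get("nodata_value", -9999.0))


def write_ascii_grid(raster: Raster, path) -> None:
    nrows, ncols = raster.data.shape
    x0, y0 = raster.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 - nrows * raster.cellsize!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Empirical line calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationPanelSet:
    """Ground panels for one band: (mean DN, known reflectance) records."""

    band: int
    records: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.records) < 2:
            raise RicePamError("need at least 2 calibration panels")

    @property
    def dn(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def reflectance(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)


class EmpiricalLineCalibrator(BaseEstimator, TransformerMixin):
    """DN -> reflectance linear calibration, fitted on ground panels.

    The model is fitted in the direction it is applied
    (``reflectance = gain * DN + offset``); fitting the inverse and
    algebraically inverting would give a different least-squares solution.

    Parameters
    ----------
    band : int or None
        Band center (nm) this calibrator belongs to, for bookkeeping.
    clip : tuple of float
        Output reflectance interval; values outside are clipped and counted.

    Attributes
    ----------
    gain_ : float
        Reflectance per DN.
    offset_ : float
        Reflectance at DN = 0.
    n_clipped_ : int
        Number of cells clipped during the most recent ``transform``.
    """

    def __init__(self, band: int | None = None, clip: tuple[float, float] = REFLECTANCE_CLIP):
        self.band = band
        self.clip = clip

    def fit(self, X, y=None):
        """Fit the line on panel DNs (X) and known reflectances (y)."""
        dn = np.asarray(X, dtype=float).ravel()
        refl = np.asarray(y, dtype=float).ravel()
        if dn.size != refl.size:
            raise RicePamError("DN and reflectance arrays differ in length")
        if dn.size < 2 or np.unique(dn).size < 2:
            raise DegeneratePanelError(
                "degenerate panel set: need >= 2 distinct DN values"
            )
        res = stats.linregress(dn, refl)
        self.gain_ = float(res.slope)
        self.offset_ = float(res.intercept)
        if not np.isfinite(self.gain_):
            raise DegeneratePanelError("non-finite gain from panel fit")
        if self.gain_ <= 0:
            warnings.warn(
                f"non-positive empirical-line gain {self.gain_} for band {self.band}",
                stacklevel=2,
            )
        self.n_clipped_ = 0
        return self

    def transform(self, X):
        """Apply gain/offset to a DN array; clip into ``self.clip``."""
        dn = np.asarray(X, dtype=float)
        refl = self.gain_ * dn + self.offset_
        lo, hi = self.clip
        out_of_range = (refl < lo) | (refl > hi)
        self.n_clipped_ = int(np.count_nonzero(out_of_range))
        if self.n_clipped_:
            logger.info("empirical line: clipped %d cells to [%g, %g]",
                        self.n_clipped_, lo, hi)
        return np.clip(refl, lo, hi)


def fit_empirical_line(panels: CalibrationPanelSet,
                       clip: tuple[float, float] = REFLECTANCE_CLIP) -> EmpiricalLineCalibrator:
    """Fit the per-band DN -> reflectance line on a panel set."""
    return EmpiricalLineCalibrator(band=panels.band, clip=clip).fit(
        panels.dn, panels.reflectance
    )


def apply_empirical_line(model: EmpiricalLineCalibrator, dn: Raster) -> tuple[Raster, int]:
    """Convert a DN raster to reflectance, preserving nodata.

    Returns the reflectance raster and the count of clipped cells.
    """
    valid = dn.mask()
    out = np.full_like(dn.data, dn.nodata, dtype=float)
    out[valid] = model.transform(dn.data[valid])
    n_clipped = model.n_clipped_
    return replace(dn, data=out), n_clipped


# ---------------------------------------------------------------------------
# Canopy height
# ---------------------------------------------------------------------------

def canopy_height(dsm: Raster, dsm_soil: Raster) -> tuple[Raster, int]:
    """Per-cell canopy height H = DSM - DSM_soil, clamped at 0.

    Small negative differences are photogrammetric noise (water surface,
    soil settling); they are clamped to 0 m and counted for QC.  Cells
    where either input is nodata are nodata in the output.

    Returns (height raster in metres, number of clamped cells).
    """
    require_aligned(dsm, dsm_soil)
    valid = dsm.mask() & dsm_soil.mask()
    diff = dsm.data - dsm_soil.data
    negative = valid & (diff < 0)
    n_clamped = int(np.count_nonzero(negative))
    if n_clamped:
        logger.info("canopy height: clamped %d negative cells to 0", n_clamped)
    out = np.full_like(diff, dsm.nodata)
    out[valid] = np.maximum(diff[valid], 0.0)
    return replace(dsm, data=out), n_clamped


# ---------------------------------------------------------------------------
# Zonal statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotROI:
    """A plot polygon in the raster's CRS."""

    plot_id: str
    polygon: BaseGeometry

    def __post_init__(self):
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise RicePamError(f"invalid or empty polygon for plot {self.plot_id}")


def load_rois(geojson: dict) -> list[PlotROI]:
    """Read PlotROIs from a GeoJSON FeatureCollection with plot_id properties."""
    rois = []
    for feature in geojson.get("features", []):
        props = feature.get("properties") or {}
        if "plot_id" not in props:
            raise RicePamError("ROI feature missing 'plot_id' property")
        rois.append(PlotROI(str(props["plot_id"]), geojson_shape(feature["geometry"])))
    return rois


def zonal_mean(grid: Raster, roi: PlotROI) -> tuple[float, int]:
    """Mean of valid cells whose centers fall inside the ROI polygon.

    Returns (mean, n_valid).  Raises :class:`EmptyROIError` when no valid
    cell center is covered.
    """
    xs, ys = grid.cell_centers()
    inside = shapely.contains_xy(roi.polygon, xs.ravel(), ys.ravel()).reshape(xs.shape)
    covered = inside & grid.mask()
    n_valid = int(np.count_nonzero(covered))
    if n_valid == 0:
        raise EmptyROIError(f"empty ROI: plot {roi.plot_id} covers no valid cells")
    return float(grid.data[covered].mean()), n_valid


def zonal_table(grid: Raster, rois: Sequence[PlotROI], value_name: str = "value") -> pd.DataFrame:
    """Zonal means for many ROIs as a tidy table (plot_id, value, n_valid)."""
    rows = [(r.plot_id, *zonal_mean(grid, r)) for r in rois]
    return pd.DataFrame(rows, columns=["plot_id", value_name, "n_valid"])
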