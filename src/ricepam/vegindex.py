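"""Vegetation indices from multispectral band reflectances.

Nine indices built from the 550/670/720/800 nm bands of a 12-band
multispectral camera: the chlorophyll indices CIgreen and CIrededge,
the normalized-difference family NDVI/GNDVI/NDRE, and MTCI, WDRVI,
OSAVI and EVI2.

The registry is data-driven: each index is a :class:`VIDefinition`
holding its required bands, its named constants and a formula callable,
so new indices can be registered without touching the evaluation code.

Note on OSAVI: the formulation implemented here uses the 720 nm
(red-edge) band in place of the canonical 670 nm red band, i.e.
``(1 + 0.16) * (R800 - R720) / (R800 + R720 + 0.16)``.  This red-edge
variant is kept deliberately; swapping in the red band would silently
change every downstream model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateReflectanceError, MissingBandError, RicePamError

#: Center wavelengths (nm) of the camera's 12 bands.
CAMERA_BANDS = frozenset({490, 520, 550, 570, 670, 680, 700, 720, 800, 850, 900, 950})

#: Indices whose accumulation behaviour makes them suitable for SPAM.
SPAM_WHITELIST = ("NDVI", "EVI2", "WDRVI", "NDRE", "OSAVI", "GNDVI")


@dataclass(frozen=True)
class SpectralSample:
    """Per-plot, per-date band reflectances.

    Parameters
    ----------
    plot_id : str
        Plot identifier.
    dat : int
        Days after transplanting (>= 0).
    reflectance : mapping of int to float
        Band center (nm) -> unitless reflectance.  Values must be finite
        and non-negative; values above 1 are allowed (calibration
        overshoot happens in practice) but trigger a warning.
    """

    plot_id: str
    dat: int
    reflectance: Mapping[int, float]

    def __post_init__(self):
        if self.dat < 0:
            raise RicePamError(f"dat must be >= 0, got {self.dat}")
        for nm, value in self.reflectance.items():
            if nm not in CAMERA_BANDS:
                raise RicePamError(f"unknown band center: {nm} nm")
            if not np.isfinite(value):
                raise RicePamError(f"non-finite reflectance at {nm} nm: {value}")
            if value < 0:
                raise RicePamError(f"negative reflectance at {nm} nm: {value}")
            if value > 1:
                warnings.warn(
                    f"reflectance {value} > 1 at {nm} nm (calibration overshoot?)",
                    stacklevel=3,
                )

    def band(self, nm: int) -> float:
        try:
            return self.reflectance[nm]
        except KeyError:
            raise MissingBandError(nm) from None


@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation index: required bands, constants, formula."""

    name: str
    required_bands: frozenset[int]
    formula: Callable[..., np.ndarray | float]
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.required_bands <= CAMERA_BANDS:
            extra = sorted(self.required_bands - CAMERA_BANDS)
            raise RicePamError(f"bands outside the camera's 12: {extra}")


def _safe_div(num, den):
    """Elementwise num/den raising on exactly-zero denominators."""
    den_arr = np.asarray(den, dtype=float)
    if np.any(den_arr == 0):
        raise DegenerateReflectanceError(
            "degenerate reflectance: zero denominator in index formula"
        )
    return num / den_arr


def _ci_green(b, p):
    return _safe_div(b[800], b[550]) - 1.0


def _ci_rededge(b, p):
    return _safe_div(b[800], b[720]) - 1.0


def _gndvi(b, p):
    return _safe_div(b[800] - b[550], b[800] + b[550])


def _ndvi(b, p):
    return _safe_div(b[800] - b[670], b[800] + b[670])


def _ndre(b, p):
    return _safe_div(b[800] - b[720], b[800] + b[720])


def _mtci(b, p):
    return _safe_div(b[800] - b[720], b[720] - b[670])


def _wdrvi(b, p):
    a = p["alpha"]
    return _safe_div(a * b[800] - b[670], a * b[800] + b[670])


def _osavi(b, p):
    # red-edge 720 nm band, not the canonical 670 nm red band
    s = p["soil_adjust"]
    return (1.0 + s) * _safe_div(b[800] - b[720], b[800] + b[720] + s)


def _evi2(b, p):
    return p["g"] * _safe_div(b[800] - b[670], p["l"] + b[800] + p["c"] * b[670])


VI_REGISTRY: dict[str, VIDefinition] = {
    d.name: d
    for d in (
        VIDefinition("CIgreen", frozenset({550, 800}), _ci_green),
        VIDefinition("CIrededge", frozenset({720, 800}), _ci_rededge),
        VIDefinition("GNDVI", frozenset({550, 800}), _gndvi),
        VIDefinition("NDVI", frozenset({670, 800}), _ndvi),
        VIDefinition("NDRE", frozenset({720, 800}), _ndre),
        VIDefinition("MTCI", frozenset({670, 720, 800}), _mtci),
        VIDefinition("WDRVI", frozenset({670, 800}), _wdrvi, {"alpha": 0.2}),
        VIDefinition("OSAVI", frozenset({720, 800}), _osavi, {"soil_adjust": 0.16}),
        VIDefinition("EVI2", frozenset({670, 800}), _evi2, {"g": 2.5, "c": 2.4, "l": 1.0}),
    )
}


def get_vi(vi: str | VIDefinition) -> VIDefinition:
    """Resolve a name to its registry entry (pass-through for definitions)."""
    if isinstance(vi, VIDefinition):
        return vi
    try:
        return VI_REGISTRY[vi]
    except KeyError:
        known = ", ".join(sorted(VI_REGISTRY))
        raise RicePamError(f"unknown vegetation index {vi!r}; known: {known}") from None


def evaluate_vi(vi: str | VIDefinition, bands: Mapping[int, np.ndarray | float],
                **param_overrides) -> np.ndarray | float:
    """Evaluate an index formula on scalar or array band values.

    This is the array-capable core used by both :func:`compute_vi` and the
    season simulator; it checks band presence but not sample invariants.
    """
    d = get_vi(vi)
    for nm in sorted(d.required_bands):
        if nm not in bands:
            raise MissingBandError(nm, d.name)
    params = {**d.params, **param_overrides}
    return d.formula(bands, params)


def compute_vi(sample: SpectralSample, vi: str | VIDefinition) -> float:
    """Compute one vegetation index for one spectral sample.

    Raises
    ------
    MissingBandError
        If a required band is absent from the sample.
    DegenerateReflectanceError
        If a denominator is exactly zero (never returns infinity).
    """
    d = get_vi(vi)
    bands = {nm: sample.band(nm) for nm in sorted(d.required_bands)}
    return float(evaluate_vi(d, bands))


def vi_batch(samples: Sequence[SpectralSample],
             vi_names: Iterable[str | VIDefinition]) -> pd.DataFrame:
    """Compute indices for many samples.

    Returns a tidy table ``(plot_id, dat, vi_name, value)`` sorted by
    (plot_id, dat, vi_name).  Errors from :func:`compute_vi` are re-raised
    with the offending row named.
    """
    if len(samples) == 0:
        raise RicePamError("vi_batch requires at least one sample")
    defs = [get_vi(v) for v in vi_names]
    rows = []
    for s in samples:
        for d in defs:
            try:
                value = compute_vi(s, d)
            except RicePamError as exc:
                raise type(exc)(
                    f"{exc} [plot_id={s.plot_id}, dat={s.dat}, vi={d.name}]"
                ) from exc
            rows.append((s.plot_id, s.dat, d.name, value))
    table = pd.DataFrame(rows, columns=["plot_id", "dat", "vi_name", "value"])
    return table.sort_values(["plot_id", "dat", "vi_name"], kind="stable").reset_index(drop=True)
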