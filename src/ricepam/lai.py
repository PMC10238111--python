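"""Leaf-area-index estimation from canopy height and a vegetation index.

The rice canopy's vertical leaf-area-density (LAD) profile is bell
shaped — small at the base and the top, largest mid-canopy.  We model it
as the quadratic through LAD(0) = 0 and LAD(H) = 0 whose peak LADmax sits
at half height:

    LAD(z) = a1 z² + a2 z,   a1 = −4 LADmax / H²,   a2 = 4 LADmax / H

Integrating over the canopy gives the closed form

    LAI = ∫₀ᴴ LAD(z) dz = (2/3) LADmax H .

Because LADmax tracks fractional vegetation cover, which a vegetation
index measures, LAI is proportional to VI·H; the estimator below fits
that proportionality as an OLS line with intercept (destructive LAI at
VI·H → 0 need not be exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateDesignError, RicePamError
from .metrics import r_squared, rmse


@dataclass(frozen=True)
class LADProfile:
    """Quadratic vertical leaf-area-density profile for one canopy.

    Attributes
    ----------
    a1 : float
        Quadratic coefficient (1/m³); non-positive for a bell shape.
    a2 : float
        Linear coefficient (1/m²).
    H : float
        Canopy height (m).
    lad_max : float
        Peak density (1/m), attained at z = H/2.
    """

    a1: float
    a2: float
    H: float
    lad_max: float

    def lad(self, z) -> np.ndarray:
        """Evaluate LAD at height(s) z (m)."""
        z = np.asarray(z, dtype=float)
        return self.a1 * z**2 + self.a2 * z


def lad_from_peak(lad_max: float, height: float) -> LADProfile:
    """The unique quadratic profile through (0,0) and (H,0) peaking at lad_max.

    Raises on non-positive height; a zero lad_max gives the null profile.
    """
    if height <= 0:
        raise RicePamError(f"invalid canopy height: {height}")
    if lad_max < 0:
        raise RicePamError(f"negative peak LAD: {lad_max}")
    a1 = -4.0 * lad_max / height**2
    a2 = 4.0 * lad_max / height
    return LADProfile(a1=a1, a2=a2, H=height, lad_max=lad_max)


def lai_from_profile(profile: LADProfile) -> float:
    """LAI as the vertical integral of the profile: (2/3)·LADmax·H."""
    return (2.0 / 3.0) * profile.lad_max * profile.H


class HVILAIRegressor(BaseEstimator, RegressorMixin):
    """LAI ~ VI·H (or VI-only) linear estimator.

    Parameters
    ----------
    vi_name : str
        Which vegetation index fills the VI slot (bookkeeping only; the
        caller supplies already-computed VI values).
    use_height : bool
        If True (default) the regressor is the product VI·H; if False it
        is VI alone, the baseline this model is compared against.

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients of LAI on the regressor.
    r2_, rmse_ : float
        In-sample diagnostics on the fitted values.
    n_obs_ : int
    """

    def __init__(self, vi_name: str = "NDVI", use_height: bool = True):
        self.vi_name = vi_name
        self.use_height = use_height

    def _regressor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.use_height:
            if X.shape[1] != 2:
                raise RicePamError(
                    f"expected 2 columns (vi, height), got {X.shape[1]}"
                )
            if np.any(X[:, 1] < 0):
                raise RicePamError("negative canopy height in design")
            return X[:, 0] * X[:, 1]
        if X.shape[1] not in (1, 2):
            raise RicePamError(f"expected 1 or 2 columns, got {X.shape[1]}")
        return X[:, 0]

    def fit(self, X, y):
        """Fit on X = (vi, height) columns and measured LAI y."""
        x = self._regressor(X)
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise RicePamError("X and y differ in length")
        if x.size < 3:
            raise DegenerateDesignError(
                f"degenerate design: need >= 3 observations, got {x.size}"
            )
        if np.ptp(x) == 0:
            raise DegenerateDesignError("degenerate design: constant regressor")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        fitted = self.slope_ * x + self.intercept_
        self.r2_ = r_squared(y, fitted, form="eq9")
        self.rmse_ = rmse(y, fitted)
        self.n_obs_ = int(x.size)
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted LAI, floored at 0 (negative LAI is meaningless)."""
        x = self._regressor(X)
        return np.maximum(self.slope_ * x + self.intercept_, 0.0)


def fit_lai_model(obs: Sequence[tuple[float, float, float]],
                  vi_name: str = "NDVI",
                  use_height: bool = True) -> HVILAIRegressor:
    """Fit the LAI estimator on (vi, height, measured LAI) triples."""
    arr = np.asarray(list(obs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise RicePamError("obs must be (vi, height, lai) triples")
    return HVILAIRegressor(vi_name=vi_name, use_height=use_height).fit(
        arr[:, :2], arr[:, 2]
    )


def predict_lai(fit: HVILAIRegressor, vi: float, height: float) -> float:
    """Predict LAI for one (vi, height) pair."""
    return float(fit.predict(np.array([[vi, height]]))[0])
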