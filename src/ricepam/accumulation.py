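"""Photosynthetic accumulation models for aboveground biomass (AGB).

Rice accumulates dry matter through photosynthesis on its green leaves,
so AGB at time t is well described by the time integral of
(photosynthetic capacity per leaf area) × (leaf area).  Substituting a
vegetation index for the net assimilation rate and VI·H for leaf area
index gives the photosynthetic accumulation model (PAM): an index

    PAM(t) = Σᵢ VI1ᵢ · VI2ᵢ · hᵢ · (tᵢ − tᵢ₋₁)        (tᵢ ≤ t)

accumulated over the flight dates since transplanting (t₀ = day 0) and
regressed linearly against destructively measured AGB.  The default
quadrature is the right-endpoint rectangle rule as written above; a
trapezoid option (with an implicit zero integrand at transplanting —
seedlings have essentially no canopy) is available and converges to the
same limit with dense sampling.

The simplified model (SPAM) needs only the target-date observation and
one near the heading stage T1, exploiting the rise-then-fall shape of
h·VI² over the season: before heading the accumulation is the area of a
triangle, after heading a triangle plus a trapezoid::

    SPAM(t) = VI_t²·h_t·(t−t₀)/2                                  t ≤ T1
    SPAM(t) = VI_T1²·h_T1·(T1−t₀)/2
              + (VI_t²·h_t + VI_T1²·h_T1)·(t−T1)/2                t > T1

SPAM is only meaningful for indices whose h·VI² trajectory actually has
that shape (NDVI, EVI2, WDRVI, NDRE, OSAVI, GNDVI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateDesignError,
    NonMonotoneTrajectoryError,
    RicePamError,
)
from .metrics import r_squared, rmse, rrmse
from .vegindex import SPAM_WHITELIST

logger = logging.getLogger(__name__)

QUADRATURES = ("rectangle_right", "trapezoid")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered per-plot observations feeding the accumulation index.

    ``t`` are observation days (days after transplanting), strictly
    increasing and all later than the reference day ``t0`` (transplanting,
    normally 0).  ``vi1`` proxies the net assimilation rate, ``vi2`` the
    LAI component, ``h`` is canopy height in metres.
    """

    plot_id: str
    t: tuple[float, ...]
    vi1: tuple[float, ...]
    vi2: tuple[float, ...]
    h: tuple[float, ...]
    t0: float = 0.0

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.vi1) == len(self.vi2) == len(self.h) == n):
            raise RicePamError("trajectory series differ in length")
        t = np.asarray(self.t, dtype=float)
        if n and np.any(np.diff(t) <= 0):
            raise NonMonotoneTrajectoryError(
                f"non-monotone trajectory for plot {self.plot_id}"
            )
        if n and t[0] <= self.t0:
            raise NonMonotoneTrajectoryError(
                f"first observation at t={t[0]} not after t0={self.t0}"
            )
        if n and np.any(np.asarray(self.h) < 0):
            raise RicePamError("negative canopy height in trajectory")

    @classmethod
    def from_arrays(cls, plot_id, t, vi1, vi2, h, t0=0.0) -> "Trajectory":
        return cls(plot_id, tuple(t), tuple(vi1), tuple(vi2), tuple(h), t0)

    def prefix(self, n: int) -> "Trajectory":
        """The trajectory truncated to its first n observations."""
        return Trajectory(self.plot_id, self.t[:n], self.vi1[:n],
                          self.vi2[:n], self.h[:n], self.t0)


@dataclass(frozen=True)
class PAMConfig:
    """Which indices fill the two PAM slots and how to integrate.

    Using the same index twice (vi1 == vi2) is the documented default:
    any one of the six whitelisted indices used in both slots performs
    on par with mixed pairs.
    """

    vi1_name: str = "NDVI"
    vi2_name: str = "NDVI"
    quadrature: str = "rectangle_right"
    spam_vi_whitelist: tuple[str, ...] = SPAM_WHITELIST

    def __post_init__(self):
        if self.quadrature not in QUADRATURES:
            raise RicePamError(
                f"unknown quadrature {self.quadrature!r}; choose from {QUADRATURES}"
            )


def pam_index_series(traj: Trajectory, cfg: PAMConfig | None = None) -> np.ndarray:
    """Cumulative PAM index evaluated at every observation date.

    Element i is the accumulation using observations 1..i+1; an empty
    trajectory yields an empty array.
    """
    cfg = cfg or PAMConfig()
    t = np.asarray(traj.t, dtype=float)
    if t.size == 0:
        return np.array([])
    integrand = (np.asarray(traj.vi1) * np.asarray(traj.vi2)
                 * np.asarray(traj.h)).astype(float)
    dt = np.diff(t, prepend=traj.t0)
    if cfg.quadrature == "rectangle_right":
        panels = integrand * dt
    else:  # trapezoid; integrand at t0 is 0 (no canopy at transplanting)
        left = np.concatenate([[0.0], integrand[:-1]])
        panels = 0.5 * (left + integrand) * dt
    return np.cumsum(panels)


def pam_index(traj: Trajectory, cfg: PAMConfig | None = None) -> float:
    """PAM accumulation index (VI²·m·day) over the whole trajectory."""
    series = pam_index_series(traj, cfg)
    return float(series[-1]) if series.size else 0.0


@dataclass(frozen=True)
class SPAMInputs:
    """The two observations SPAM needs: target date t and heading date T1."""

    t: float
    vi_t: float
    h_t: float
    T1: float
    vi_T1: float
    h_T1: float
    t0: float = 0.0

    def __post_init__(self):
        if self.T1 <= self.t0:
            raise RicePamError(f"heading T1={self.T1} not after t0={self.t0}")
        if self.t <= self.t0:
            raise RicePamError(
                f"target precedes transplanting: t={self.t} <= t0={self.t0}"
            )


def spam_index(inp: SPAMInputs) -> float:
    """Triangle (pre-heading) or triangle + trapezoid (post-heading) area."""
    if inp.t <= inp.T1:
        return inp.vi_t**2 * inp.h_t * (inp.t - inp.t0) / 2.0
    pre = inp.vi_T1**2 * inp.h_T1 * (inp.T1 - inp.t0) / 2.0
    post = (inp.vi_t**2 * inp.h_t + inp.vi_T1**2 * inp.h_T1) * (inp.t - inp.T1) / 2.0
    return pre + post


def heading_observation(traj: Trajectory, heading_dat: float,
                        window: float = 5.0) -> tuple[float, float, float]:
    """(t, vi2, h) of the flight nearest the heading stage.

    Looks within ±window days of ``heading_dat`` (flights rarely land
    exactly on heading); raises if none qualifies.  The vi2 series fills
    the SPAM VI slot.
    """
    t = np.asarray(traj.t, dtype=float)
    if t.size == 0:
        raise RicePamError("empty trajectory")
    i = int(np.argmin(np.abs(t - heading_dat)))
    if abs(t[i] - heading_dat) > window:
        raise RicePamError(
            f"no observation within {window} days of heading DAT {heading_dat} "
            f"for plot {traj.plot_id}"
        )
    return float(t[i]), float(traj.vi2[i]), float(traj.h[i])


def spam_index_series(traj: Trajectory, heading_dat: float,
                      window: float = 5.0,
                      vi_name: str | None = None,
                      whitelist: tuple[str, ...] = SPAM_WHITELIST) -> np.ndarray:
    """SPAM index at every observation date of a trajectory.

    The same VI series (vi2) fills both the target and heading slots; the
    heading observation is the flight nearest heading_dat within the
    window.  ``vi_name`` is validated against the whitelist when given.
    """
    if vi_name is not None and vi_name not in whitelist:
        raise RicePamError(
            f"{vi_name} is not SPAM-suitable; choose from {whitelist}"
        )
    t_h, vi_h, h_h = heading_observation(traj, heading_dat, window)
    out = np.empty(len(traj.t))
    for i, (t_i, vi_i, h_i) in enumerate(zip(traj.t, traj.vi2, traj.h)):
        out[i] = spam_index(SPAMInputs(
            t=t_i, vi_t=vi_i, h_t=h_i, T1=t_h, vi_T1=vi_h, h_T1=h_h, t0=traj.t0
        ))
    return out


class AGBRegressor(BaseEstimator, RegressorMixin):
    """Linear calibration of an accumulation index against measured AGB.

    Simple OLS with intercept of W (g/m²) on the PAM or SPAM index, the
    final stage of the estimation chain.

    Attributes
    ----------
    slope_ : float
        g/m² per index unit.
    intercept_ : float
        g/m².
    r2_, rmse_, rrmse_ : float
        In-sample diagnostics on the fitted values (eq9 R² form).
    n_floored_ : int
        Predictions clamped to 0 during the most recent ``predict``.
    """

    def __init__(self, index_kind: str = "PAM"):
        self.index_kind = index_kind

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise RicePamError("index and AGB arrays differ in length")
        if x.size < 3:
            raise DegenerateDesignError(
                f"degenerate design: need >= 3 pairs, got {x.size}"
            )
        if np.ptp(x) == 0:
            raise DegenerateDesignError("degenerate design: constant index")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        fitted = self.slope_ * x + self.intercept_
        self.r2_ = r_squared(y, fitted, form="eq9")
        self.rmse_ = rmse(y, fitted)
        self.rrmse_ = rrmse(y, fitted)
        self.n_obs_ = int(x.size)
        self.n_floored_ = 0
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted AGB (g/m²), floored at 0 with a logged count.

        Raw linear height-era models are known to go negative early in
        the season; the floor keeps reported biomass physical.
        """
        x = np.asarray(X, dtype=float).ravel()
        raw = self.slope_ * x + self.intercept_
        self.n_floored_ = int(np.count_nonzero(raw < 0))
        if self.n_floored_:
            logger.info("AGB prediction: floored %d negative values", self.n_floored_)
        return np.maximum(raw, 0.0)


def fit_agb_model(pairs: Sequence[tuple[float, float]],
                  index_kind: str = "PAM") -> AGBRegressor:
    """Fit the AGB line on (index, measured W) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise RicePamError("pairs must be (index, W) tuples")
    return AGBRegressor(index_kind=index_kind).fit(arr[:, 0], arr[:, 1])


def predict_agb(model: AGBRegressor, index) -> float | np.ndarray:
    """Predict AGB for one index value or an array of them."""
    scalar = np.isscalar(index)
    out = model.predict(np.atleast_1d(index))
    return float(out[0]) if scalar else out
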