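"""Synthetic multi-cultivar rice seasons for end-to-end testing.

No field campaign ships with this package, so the simulator generates
seasons with the statistical structure the estimation chain assumes:

* logistic canopy height growth (anchored to ~0 at transplanting);
* fractional green cover rising logistically to closure;
* a panicle fraction that grows linearly after the heading stage T1
  (capped at 0.5) — panicles are redder than leaves, so their emergence
  drags the vegetation indices down after heading;
* canopy reflectance as a three-endmember linear mixture of soil, green
  leaf and panicle spectra at 550/670/720/800 nm, which reproduces the
  rise-then-fall VI trajectories mechanistically instead of hand-drawing
  them;
* true LAI from the bell-shaped leaf-area-density profile, with peak
  density proportional to green cover;
* true aboveground biomass as the conversion efficiency ``c_conv`` times
  the day-by-day accumulation of NDVI²·height (the photosynthetic proxy
  integrated over the season).

Observations are the daily truth sampled on a flight calendar with
multiplicative lognormal noise (traits are positive and errors roughly
proportional).  Everything is driven by an explicit seed; the same seed
reproduces the same season bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import RicePamError
from .vegindex import VI_REGISTRY, evaluate_vi

#: The 13-date flight calendar of a dense single-season campaign
#: (days after transplanting).
DEFAULT_SCHEDULE = (17, 23, 27, 35, 43, 48, 53, 58, 63, 68, 74, 81, 86)

MIXTURE_BANDS = (550, 670, 720, 800)


@dataclass(frozen=True)
class EndmemberSpectra:
    """Reflectance of soil, green leaf and panicle at the four VI bands."""

    soil: Mapping[int, float] = field(
        default_factory=lambda: {550: 0.10, 670: 0.15, 720: 0.20, 800: 0.25})
    leaf: Mapping[int, float] = field(
        default_factory=lambda: {550: 0.08, 670: 0.04, 720: 0.25, 800: 0.50})
    panicle: Mapping[int, float] = field(
        default_factory=lambda: {550: 0.25, 670: 0.20, 720: 0.30, 800: 0.45})

    def __post_init__(self):
        for member in (self.soil, self.leaf, self.panicle):
            if set(member) != set(MIXTURE_BANDS):
                raise RicePamError(f"endmember must cover bands {MIXTURE_BANDS}")
        if not self.leaf[670] < self.leaf[800]:
            raise RicePamError("leaf endmember must have low red, high NIR")
        if not self.panicle[670] > self.leaf[670]:
            raise RicePamError(
                "panicle red reflectance must exceed leaf's "
                "(it drives the post-heading VI decline)"
            )


@dataclass(frozen=True)
class CultivarParams:
    """Phenology, growth and noise parameters for one cultivar/plot.

    Units: heights in m, times in days after transplanting, rates in
    1/day, ``c_conv`` in g/m² per (VI²·m·day), noise levels as relative
    coefficients of variation.
    """

    h_max: float = 1.0          # asymptotic canopy height (m)
    k_h: float = 0.15           # logistic height growth rate (1/day)
    t_mid: float = 45.0         # height inflection day
    T1: float = 62.0            # heading stage (DAT)
    cover_rate: float = 0.15    # canopy-closure logistic rate (1/day)
    cover_mid: float = 30.0     # canopy-closure midpoint (DAT)
    panicle_rate: float = 0.02  # panicle fraction gained per day after T1
    c_conv: float = 4.5         # photosynthate conversion efficiency
    lad_peak: float = 4.5       # peak leaf-area density at full cover (1/m)
    noise_cv_vi: float = 0.05   # reflectance observation noise
    noise_cv_h: float = 0.05    # height observation noise
    noise_cv_agb: float = 0.05  # destructive measurement noise (LAI and AGB)

    def __post_init__(self):
        for name in ("h_max", "k_h", "cover_rate", "panicle_rate", "c_conv"):
            if getattr(self, name) <= 0:
                raise RicePamError(f"{name} must be positive")
        if self.T1 <= 0:
            raise RicePamError("heading T1 must be within the season")


#: Uniform draw ranges for the multi-cultivar benchmark.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "h_max": (0.8, 1.2),
    "k_h": (0.12, 0.18),
    "t_mid": (40.0, 50.0),
    "T1": (55.0, 70.0),
    "cover_rate": (0.12, 0.18),
    "cover_mid": (25.0, 35.0),
    "panicle_rate": (0.015, 0.03),
    "c_conv": (3.0, 6.0),
    "lad_peak": (3.5, 5.5),
}


@dataclass
class SimSeason:
    """One simulated plot-season: daily truth plus noisy scheduled samples."""

    plot_id: str
    params: CultivarParams
    truth: pd.DataFrame
    observations: pd.DataFrame
    seed: int


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(0.0, np.sqrt(sigma2), size) - sigma2 / 2.0)


def _daily_truth(params: CultivarParams, spectra: EndmemberSpectra,
                 season_end: int) -> pd.DataFrame:
    t = np.arange(1, season_end + 1, dtype=float)
    h_raw = params.h_max * expit(params.k_h * (t - params.t_mid))
    h0 = params.h_max * expit(-params.k_h * params.t_mid)
    h_true = np.maximum(h_raw - h0, 0.0)

    cover = expit(params.cover_rate * (t - params.cover_mid))
    panicle = np.minimum(params.panicle_rate * np.maximum(t - params.T1, 0.0), 0.5)

    bands = {}
    for nm in MIXTURE_BANDS:
        canopy = (1.0 - panicle) * spectra.leaf[nm] + panicle * spectra.panicle[nm]
        bands[nm] = (1.0 - cover) * spectra.soil[nm] + cover * canopy

    table = pd.DataFrame({"t": t.astype(int), "h_true": h_true,
                          "cover": cover, "panicle": panicle})
    for nm in MIXTURE_BANDS:
        table[f"r{nm}"] = bands[nm]
    for name in VI_REGISTRY:
        table[f"vi_{name}"] = evaluate_vi(name, bands)

    table["lai_true"] = (2.0 / 3.0) * params.lad_peak * cover * h_true
    integrand = table["vi_NDVI"].to_numpy() ** 2 * h_true  # daily photosynthate
    table["agb_true"] = params.c_conv * np.cumsum(integrand)
    return table


def simulate_season(params: CultivarParams | None = None,
                    spectra: EndmemberSpectra | None = None,
                    schedule: Sequence[int] = DEFAULT_SCHEDULE,
                    seed: int = 0,
                    season_end: int = 90,
                    plot_id: str = "P01") -> SimSeason:
    """Simulate one plot-season and sample it on the flight calendar.

    Raises if any schedule day falls outside (0, season_end].
    """
    params = params or CultivarParams()
    spectra = spectra or EndmemberSpectra()
    schedule = tuple(int(d) for d in schedule)
    if any(d <= 0 or d > season_end for d in schedule):
        raise RicePamError(
            f"schedule days must lie in (0, {season_end}], got {schedule}"
        )

    truth = _daily_truth(params, spectra, season_end)
    rng = np.random.default_rng(seed)

    rows = truth.set_index("t").loc[list(schedule)]
    n = len(schedule)
    obs = pd.DataFrame({"plot_id": plot_id, "dat": list(schedule)})
    for nm in MIXTURE_BANDS:
        obs[f"r{nm}"] = (rows[f"r{nm}"].to_numpy()
                         * _lognormal_factors(rng, params.noise_cv_vi, n))
    obs["height_m"] = (rows["h_true"].to_numpy()
                       * _lognormal_factors(rng, params.noise_cv_h, n))
    obs["lai"] = (rows["lai_true"].to_numpy()
                  * _lognormal_factors(rng, params.noise_cv_agb, n))
    obs["agb"] = (rows["agb_true"].to_numpy()
                  * _lognormal_factors(rng, params.noise_cv_agb, n))

    truth = truth.copy()
    truth.insert(0, "plot_id", plot_id)
    return SimSeason(plot_id=plot_id, params=params, truth=truth,
                     observations=obs, seed=seed)


@dataclass
class Benchmark:
    """A multi-plot benchmark: seasons plus tidy pooled tables."""

    seasons: list[SimSeason]
    observations: pd.DataFrame
    truth: pd.DataFrame
    params: pd.DataFrame  # one row per plot, includes heading DAT


def generate_benchmark(n_plots: int = 48,
                       cultivar_spread: Mapping[str, tuple[float, float]] | None = None,
                       schedule: Sequence[int] = DEFAULT_SCHEDULE,
                       seed: int = 0,
                       season_end: int = 90,
                       noise_cv_vi: float = 0.05,
                       noise_cv_h: float = 0.05,
                       noise_cv_agb: float = 0.05) -> Benchmark:
    """Draw per-plot cultivar parameters and simulate every plot.

    Defaults mirror a dense 48-cultivar campaign: 48 plots × 13 flight
    dates = 624 observation rows.  Parameters are drawn uniformly within
    ``cultivar_spread`` (default :data:`DEFAULT_RANGES`) from a generator
    seeded with ``seed``; each plot then gets its own child seed.
    """
    if n_plots < 1:
        raise RicePamError("n_plots must be >= 1")
    ranges = dict(DEFAULT_RANGES)
    if cultivar_spread:
        ranges.update(cultivar_spread)
    rng = np.random.default_rng(seed)

    seasons = []
    param_rows = []
    for i in range(n_plots):
        drawn = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
        params = CultivarParams(**drawn, noise_cv_vi=noise_cv_vi,
                                noise_cv_h=noise_cv_h, noise_cv_agb=noise_cv_agb)
        plot_id = f"P{i + 1:02d}"
        child_seed = int(rng.integers(0, 2**31 - 1))
        season = simulate_season(params, schedule=schedule, seed=child_seed,
                                 season_end=season_end, plot_id=plot_id)
        seasons.append(season)
        param_rows.append({"plot_id": plot_id, "heading_dat": params.T1,
                           "sim_seed": child_seed, **asdict(params)})

    observations = pd.concat([s.observations for s in seasons], ignore_index=True)
    truth = pd.concat([s.truth for s in seasons], ignore_index=True)
    params_table = pd.DataFrame(param_rows)
    return Benchmark(seasons=seasons, observations=observations,
                     truth=truth, params=params_table)
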