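"""Standard model comparisons on the synthetic benchmark.

These are the evaluations the package runs end to end: calibrate each
AGB model (PAM, SPAM, single-date VI, height) on the pooled plot-date
samples of one benchmark realization, and the LAI model comparison
(VI·H versus VI-only).  All R² values are the regression-sum-of-squares
form on in-sample fitted values, which for OLS lines equals the
conventional form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accumulation import AGBRegressor, PAMConfig, Trajectory, fit_agb_model, pam_index_series
from .lai import HVILAIRegressor
from .pipeline import add_vi_columns, join_measurements, pam_table, spam_table
from .synthetic import Benchmark, CultivarParams, generate_benchmark, simulate_season


def fit_pam(bench: Benchmark, vi: str = "NDVI",
            quadrature: str = "rectangle_right") -> AGBRegressor:
    """PAM with one index in both slots, calibrated on all plot-dates."""
    cfg = PAMConfig(vi1_name=vi, vi2_name=vi, quadrature=quadrature)
    table = join_measurements(pam_table(bench.observations, cfg),
                              bench.observations, "agb")
    return fit_agb_model(table[["pam_index", "agb"]].to_numpy(), index_kind="PAM")


def fit_spam(bench: Benchmark, vi: str = "NDVI", window: float = 5.0) -> AGBRegressor:
    """SPAM with per-plot heading DATs taken from the benchmark phenology."""
    heading = dict(zip(bench.params["plot_id"], bench.params["heading_dat"]))
    table = join_measurements(spam_table(bench.observations, vi, heading, window),
                              bench.observations, "agb")
    return fit_agb_model(table[["spam_index", "agb"]].to_numpy(), index_kind="SPAM")


def fit_vi_model(bench: Benchmark, vi: str = "NDVI") -> AGBRegressor:
    """Baseline: AGB regressed on the single-date VI value alone."""
    obs = add_vi_columns(bench.observations, [vi])
    return fit_agb_model(obs[[f"vi_{vi}", "agb"]].to_numpy(), index_kind="VI")


def fit_height_model(bench: Benchmark) -> AGBRegressor:
    """Baseline: AGB regressed on single-date canopy height."""
    return fit_agb_model(bench.observations[["height_m", "agb"]].to_numpy(),
                         index_kind="H")


def fit_lai_models(bench: Benchmark, vi: str = "NDVI") -> tuple[HVILAIRegressor, HVILAIRegressor]:
    """(VI·H model, VI-only model) for LAI on the pooled observations."""
    obs = add_vi_columns(bench.observations, [vi])
    X = obs[[f"vi_{vi}", "height_m"]].to_numpy(dtype=float)
    y = obs["lai"].to_numpy(dtype=float)
    with_h = HVILAIRegressor(vi_name=vi, use_height=True).fit(X, y)
    vi_only = HVILAIRegressor(vi_name=vi, use_height=False).fit(X[:, :1], y)
    return with_h, vi_only


@dataclass(frozen=True)
class ModelComparison:
    """R² of the four AGB models plus the LAI model pair, one realization."""

    pam_r2: float
    spam_r2: float
    vi_r2: float
    height_r2: float
    lai_vih_r2: float
    lai_vi_r2: float


def compare_models(seed: int, vi: str = "NDVI", n_plots: int = 48,
                   noise_cv: float = 0.05) -> ModelComparison:
    """Run the full comparison on one benchmark realization."""
    bench = generate_benchmark(n_plots=n_plots, seed=seed,
                               noise_cv_vi=noise_cv, noise_cv_h=noise_cv,
                               noise_cv_agb=noise_cv)
    lai_vih, lai_vi = fit_lai_models(bench, vi)
    return ModelComparison(
        pam_r2=fit_pam(bench, vi).r2_,
        spam_r2=fit_spam(bench, vi).r2_,
        vi_r2=fit_vi_model(bench, vi).r2_,
        height_r2=fit_height_model(bench).r2_,
        lai_vih_r2=lai_vih.r2_,
        lai_vi_r2=lai_vi.r2_,
    )


def conversion_recovery(seed: int, noise_cv: float = 0.0,
                        season_end: int = 90) -> float:
    """Relative bias of the fitted AGB slope against the true ``c_conv``.

    Uses a daily observation schedule so the rectangle-rule accumulation
    matches the simulator's daily truth integral; any residual bias then
    comes from observation noise alone.
    """
    params = CultivarParams(noise_cv_vi=noise_cv, noise_cv_h=noise_cv,
                            noise_cv_agb=noise_cv)
    season = simulate_season(params, schedule=range(1, season_end + 1),
                             seed=seed, season_end=season_end)
    obs = add_vi_columns(season.observations, ["NDVI"])
    traj = Trajectory.from_arrays(
        season.plot_id,
        obs["dat"].to_numpy(dtype=float),
        obs["vi_NDVI"].to_numpy(dtype=float),
        obs["vi_NDVI"].to_numpy(dtype=float),
        obs["height_m"].to_numpy(dtype=float),
    )
    index = pam_index_series(traj, PAMConfig())
    model = fit_agb_model(np.column_stack([index, obs["agb"].to_numpy()]))
    return (model.slope_ - params.c_conv) / params.c_conv
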