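"""Glue between tidy observation tables and the model layer.

The observation schema is one row per plot × flight date with columns
``plot_id, dat, r<nm>... , height_m`` and optionally the destructive
measurements ``lai`` and ``agb``.  These helpers compute vegetation-index
columns, assemble per-plot trajectories and evaluate the accumulation
indices for every plot-date.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accumulation import (
    PAMConfig,
    Trajectory,
    pam_index_series,
    spam_index_series,
)
from .errors import RicePamError
from .vegindex import evaluate_vi

_BAND_COL = re.compile(r"^r(\d{3})$")


def band_columns(obs: pd.DataFrame) -> dict[int, str]:
    """Map band center (nm) -> column name for every r<nm> column."""
    return {int(m.group(1)): c for c in obs.columns if (m := _BAND_COL.match(c))}


def add_vi_columns(obs: pd.DataFrame, vi_names: Sequence[str]) -> pd.DataFrame:
    """Return a copy of obs with a ``vi_<name>`` column per requested index."""
    cols = band_columns(obs)
    bands = {nm: obs[c].to_numpy(dtype=float) for nm, c in cols.items()}
    out = obs.copy()
    for name in vi_names:
        out[f"vi_{name}"] = evaluate_vi(name, bands)
    return out


def plot_trajectories(obs: pd.DataFrame, vi1: str, vi2: str,
                      height_col: str = "height_m",
                      t0: float = 0.0) -> dict[str, Trajectory]:
    """Build one Trajectory per plot from an observation table."""
    for col in ("plot_id", "dat", height_col):
        if col not in obs.columns:
            raise RicePamError(f"observation table missing column {col!r}")
    table = add_vi_columns(obs, sorted({vi1, vi2}))
    trajectories = {}
    for plot_id, grp in table.sort_values("dat").groupby("plot_id", sort=True):
        trajectories[str(plot_id)] = Trajectory.from_arrays(
            str(plot_id),
            grp["dat"].to_numpy(dtype=float),
            grp[f"vi_{vi1}"].to_numpy(dtype=float),
            grp[f"vi_{vi2}"].to_numpy(dtype=float),
            grp[height_col].to_numpy(dtype=float),
            t0=t0,
        )
    return trajectories


def pam_table(obs: pd.DataFrame, cfg: PAMConfig | None = None,
              t0: float = 0.0) -> pd.DataFrame:
    """PAM index at every plot-date: columns (plot_id, dat, pam_index)."""
    cfg = cfg or PAMConfig()
    trajs = plot_trajectories(obs, cfg.vi1_name, cfg.vi2_name, t0=t0)
    frames = []
    for plot_id, traj in trajs.items():
        frames.append(pd.DataFrame({
            "plot_id": plot_id,
            "dat": np.asarray(traj.t, dtype=int),
            "pam_index": pam_index_series(traj, cfg),
        }))
    return pd.concat(frames, ignore_index=True)


def spam_table(obs: pd.DataFrame, vi: str,
               heading: Mapping[str, float] | float,
               window: float = 5.0,
               t0: float = 0.0) -> pd.DataFrame:
    """SPAM index at every plot-date.

    ``heading`` is either a single heading DAT for all plots or a mapping
    plot_id -> heading DAT (per-cultivar phenology).
    """
    trajs = plot_trajectories(obs, vi, vi, t0=t0)
    frames = []
    for plot_id, traj in trajs.items():
        if isinstance(heading, Mapping):
            if plot_id not in heading:
                raise RicePamError(f"no heading DAT for plot {plot_id}")
            t1 = float(heading[plot_id])
        else:
            t1 = float(heading)
        frames.append(pd.DataFrame({
            "plot_id": plot_id,
            "dat": np.asarray(traj.t, dtype=int),
            "spam_index": spam_index_series(traj, t1, window=window, vi_name=vi),
        }))
    return pd.concat(frames, ignore_index=True)


def join_measurements(index_table: pd.DataFrame, obs: pd.DataFrame,
                      value_col: str = "agb") -> pd.DataFrame:
    """Attach a measured column from obs to an index table on (plot_id, dat)."""
    if value_col not in obs.columns:
        raise RicePamError(f"observation table missing column {value_col!r}")
    merged = index_table.merge(
        obs[["plot_id", "dat", value_col]], on=["plot_id", "dat"], how="inner"
    )
    if merged.empty:
        raise RicePamError("no (plot_id, dat) overlap between tables")
    return merged
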