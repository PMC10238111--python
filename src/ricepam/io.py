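"""Table readers, config loading and small format helpers.

Time is handled in days after transplanting (DAT, integer, transplanting
= day 0) everywhere inside the package; observation tables may instead
carry an ISO ``date`` column, which is converted once at ingestion given
the transplanting date.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Sequence

import pandas as pd
import yaml

from .calibration import CalibrationPanelSet
from .errors import RicePamError
from .vegindex import SpectralSample
from .pipeline import band_columns

#: Recognised config sections and their allowed keys.
CONFIG_SCHEMA: dict[str, set[str]] = {
    "paths": {"rasters", "rois", "tables", "output_dir"},
    "model": {"vi1", "vi2", "quadrature", "spam_window", "r2_form", "heading_csv"},
    "simulation": {"n_plots", "schedule", "seed", "season_end",
                   "noise_cv_vi", "noise_cv_h", "noise_cv_agb"},
    "date_join_tolerance": set(),
}


def load_config(path) -> dict:
    """Load a YAML run config, rejecting unknown sections and keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise RicePamError("config must be a mapping")
    for section, content in cfg.items():
        if section not in CONFIG_SCHEMA:
            raise RicePamError(f"unknown config section: {section!r}")
        allowed = CONFIG_SCHEMA[section]
        if allowed and isinstance(content, dict):
            for key in content:
                if key not in allowed:
                    raise RicePamError(
                        f"unknown config key: {section}.{key!r}"
                    )
    return cfg


def read_observations(path, transplanting: str | None = None) -> pd.DataFrame:
    """Read an observation CSV; derive ``dat`` from ``date`` if needed."""
    obs = pd.read_csv(path)
    if "dat" not in obs.columns:
        if "date" not in obs.columns:
            raise RicePamError("observation table needs a 'dat' or 'date' column")
        if transplanting is None:
            raise RicePamError(
                "a 'date' column requires the transplanting date to derive DAT"
            )
        t0 = _dt.date.fromisoformat(transplanting)
        obs["dat"] = [
            (_dt.date.fromisoformat(str(d)) - t0).days for d in obs["date"]
        ]
    if "plot_id" not in obs.columns:
        raise RicePamError("observation table needs a 'plot_id' column")
    obs["plot_id"] = obs["plot_id"].astype(str)
    obs["dat"] = obs["dat"].astype(int)
    return obs


def observations_to_samples(obs: pd.DataFrame) -> list[SpectralSample]:
    """One SpectralSample per row, from the r<nm> band columns."""
    cols = band_columns(obs)
    if not cols:
        raise RicePamError("no r<nm> band columns found")
    return [
        SpectralSample(
            plot_id=str(row["plot_id"]),
            dat=int(row["dat"]),
            reflectance={nm: float(row[c]) for nm, c in cols.items()},
        )
        for _, row in obs.iterrows()
    ]


def read_panels(path, band: int) -> CalibrationPanelSet:
    """Read a panel CSV ``band,mean_dn,reflectance`` for one band."""
    table = pd.read_csv(path)
    for col in ("band", "mean_dn", "reflectance"):
        if col not in table.columns:
            raise RicePamError(f"panel table missing column {col!r}")
    rows = table[table["band"].astype(int) == int(band)]
    if rows.empty:
        raise RicePamError(f"no panel records for band {band}")
    records = tuple(
        (float(r["mean_dn"]), float(r["reflectance"])) for _, r in rows.iterrows()
    )
    return CalibrationPanelSet(band=int(band), records=records)


def read_heading(path) -> dict[str, float]:
    """Read per-plot (or per-cultivar) heading DATs: ``plot_id,heading_dat``."""
    table = pd.read_csv(path)
    key = "plot_id" if "plot_id" in table.columns else "cultivar"
    if key not in table.columns or "heading_dat" not in table.columns:
        raise RicePamError(
            "heading table needs columns 'plot_id' (or 'cultivar') and 'heading_dat'"
        )
    return {str(r[key]): float(r["heading_dat"]) for _, r in table.iterrows()}


def nearest_dat_join(left: pd.DataFrame, right: pd.DataFrame,
                     tolerance: int = 2,
                     suffix: str = "_meas") -> pd.DataFrame:
    """Join two plot×date tables on plot_id and nearest DAT within tolerance.

    Flight and destructive-sampling calendars are typically offset by
    0-2 days; rows with no partner within the tolerance are dropped.
    """
    pieces = []
    for plot_id, lgrp in left.groupby("plot_id", sort=True):
        rgrp = right[right["plot_id"] == plot_id]
        if rgrp.empty:
            continue
        merged = pd.merge_asof(
            lgrp.sort_values("dat"),
            rgrp.sort_values("dat").rename(columns={"dat": f"dat{suffix}"}),
            left_on="dat", right_on=f"dat{suffix}",
            direction="nearest", tolerance=tolerance,
            suffixes=("", suffix),
        )
        pieces.append(merged.dropna(subset=[f"dat{suffix}"]))
    if not pieces:
        raise RicePamError("nearest-DAT join produced no rows")
    out = pd.concat(pieces, ignore_index=True)
    return out.drop(columns=[c for c in (f"plot_id{suffix}",) if c in out])


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def schedule_from_string(text: str) -> tuple[int, ...]:
    """Parse a comma-separated DAT list like '17,23,27'."""
    try:
        return tuple(int(x) for x in str(text).split(","))
    except ValueError:
        raise RicePamError(f"bad schedule: {text!r}") from None
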