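"""Thermal-regime covariates from drift trajectories and origin SST.

Marine phytoplankton drift with ocean currents, so the thermal
environment a strain experienced is summarized from replicate
backwards-in-time trajectories: per replicate, the median and
interquartile range of daily temperature and latitude over the first
``duration`` days; then a mean across replicates weighted by the
number of days each trajectory actually contributed (some trajectories
are shorter than the requested duration).  The per-replicate-then-
weighted-average order matters and is enforced here -- pooling all
days first would give different (wrong) answers.  Origin statistics
are plain median/IQR over the full daily sea-surface-temperature
series of the isolation location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DURATIONS = (50, 150, 250, 350, 500)


@dataclass(frozen=True)
class EnvSummary:
    """Weighted trajectory statistics for one (location, depth, duration)."""

    location_id: str
    depth_m: float
    duration: int
    t_med: float
    t_iqr: float
    lat_med: float
    lat_iqr: float
    n_replicates: int


def _iqr(x: np.ndarray) -> float:
    # linear interpolation between order statistics (numpy default)
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def summarize_origin(daily_sst) -> tuple[float, float]:
    """Median and IQR of a location's daily SST series (degC)."""
    x = np.asarray(daily_sst, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty SST series")
    return float(np.median(x)), _iqr(x)


def summarize_trajectories(traj: pd.DataFrame, duration: int,
                           require_standard_duration: bool = True) -> list[EnvSummary]:
    """Per-replicate medians/IQRs, then a length-weighted mean.

    ``traj`` columns: ``location_id, depth_m, replicate_id, day,
    temperature_C, latitude_deg`` with day indices starting at 1.  For
    each replicate only the first ``duration`` days are used (or the
    full, shorter trajectory); the replicate's weight is the number of
    days actually used.  Empty replicates are skipped with a log
    entry.  Returns one :class:`EnvSummary` per (location, depth).
    """
    if require_standard_duration and duration not in DURATIONS:
        raise ValueError(f"duration must be one of {DURATIONS}")
    out: list[EnvSummary] = []
    for (loc, depth), grp in traj.groupby(["location_id", "depth_m"], sort=True):
        stats = []  # (weight, t_med, t_iqr, l_med, l_iqr)
        for rep, rgrp in grp.groupby("replicate_id", sort=True):
            sel = rgrp[rgrp["day"] <= duration]
            if len(sel) == 0:
                logger.info("empty replicate %s at %s/%sm skipped",
                            rep, loc, depth)
                continue
            t = sel["temperature_C"].to_numpy(float)
            l = sel["latitude_deg"].to_numpy(float)
            stats.append((len(sel), float(np.median(t)), _iqr(t),
                          float(np.median(l)), _iqr(l)))
        if not stats:
            continue
        w = np.array([s[0] for s in stats], dtype=float)
        arr = np.array([s[1:] for s in stats], dtype=float)
        wm = (w[:, None] * arr).sum(0) / w.sum()
        out.append(EnvSummary(
            location_id=str(loc), depth_m=float(depth), duration=duration,
            t_med=float(wm[0]), t_iqr=float(wm[1]),
            lat_med=float(wm[2]), lat_iqr=float(wm[3]),
            n_replicates=len(stats)))
    return out


def env_covariate_table(traj: pd.DataFrame, sst: pd.DataFrame | None = None,
                        durations=DURATIONS) -> pd.DataFrame:
    """Full covariate table across durations, merged with origin stats.

    ``sst`` columns: ``location_id, date, sst_C``.  Column names follow
    the covariate naming used by the marine model variants:
    ``t_med_{depth}m_{duration}d`` etc., plus ``t_med_orig`` and
    ``t_iqr_orig`` per location.
    """
    rows = []
    for dur in durations:
        for s in summarize_trajectories(traj, dur):
            rows.append({
                "location_id": s.location_id, "depth_m": s.depth_m,
                "duration": s.duration, "t_med": s.t_med, "t_iqr": s.t_iqr,
                "lat_med": s.lat_med, "lat_iqr": s.lat_iqr,
                "n_replicates": s.n_replicates,
            })
    df = pd.DataFrame(rows)
    if sst is not None:
        orig = (
            sst.groupby("location_id")["sst_C"]
            .apply(lambda x: pd.Series(summarize_origin(x),
                                       index=["t_med_orig", "t_iqr_orig"]))
            .unstack()
            .reset_index()
        )
        df = df.merge(orig, on="location_id", how="left")
    return df
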