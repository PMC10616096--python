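"""Stage-level environmental covariates and reproductive stress indices.

Daily crop-model style series are summarized into per-stage environmental
covariates (ECs), and into two reproductive-stress indices:

* SDR — mean daily crop water supply/demand ratio over the reproductive
  window (flag-leaf appearance through end of grain fill), with demand
  ``Eo x green-cover x 2`` and daily ratios clipped at 4;
* HI30 — number of window days with maximum temperature strictly above 30 degC.

Year-locations are flagged as drought-stressed when ``SDR <= 0.54``
(inclusive) and heat-stressed when ``HI30 > 36`` (strict).

A sequential sums-of-squares ANOVA partitions each EC column into region,
location-within-region, and residual year-location shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StressIndices", "aggregate_soil_layers", "stage_average", "compute_sdr",
    "compute_hi30", "stress_flags", "tune_juvenile_gdd", "ec_anova",
    "ec_anova_stratified", "stress_indices",
]

SDR_CLIP = 4.0
CROP_FACTOR = 2.0
SDR_THRESHOLD = 0.54
HI30_THRESHOLD = 36


@dataclass
class StressIndices:
    """Reproductive-window stress summary of one year-location."""

    sdr: float
    hi30: int
    drought: bool
    heat: bool
    combined: bool


def aggregate_soil_layers(values: np.ndarray, weights: np.ndarray):
    """Accessibility-weighted mean across soil layers, per day.

    ``values`` and ``weights`` are layers x days; the daily aggregate is
    ``sum_l w_l v_l / sum_l w_l``, or 0 (flagged) on days with all-zero
    weights.  Negative weights raise ``ValueError``.

    Returns ``(daily aggregate, all-zero-weight flag per day)``.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if (weights < 0).any():
        raise ValueError("accessibility weights must be non-negative")
    wsum = weights.sum(axis=0)
    zero = wsum == 0
    agg = np.zeros(values.shape[1])
    nz = ~zero
    agg[nz] = (weights[:, nz] * values[:, nz]).sum(axis=0) / wsum[nz]
    return agg, zero


def stage_average(daily: pd.DataFrame, stage_bounds) -> pd.Series:
    """Per-stage means of daily EC-type series.

    ``daily`` is days x types; ``stage_bounds`` holds S+1 increasing day
    indices delimiting S half-open stages ``[b_s, b_{s+1})`` (the last stage
    is closed at the series end by construction of the bounds).  Output is a
    Series named ``<TYPE>_<stage>`` with stages numbered from 1 — with 21
    types and 9 stages, exactly 189 values.  Empty stages raise ``ValueError``.
    """
    bounds = np.asarray(stage_bounds, int)
    out = {}
    for s in range(len(bounds) - 1):
        lo, hi = bounds[s], bounds[s + 1]
        if hi <= lo:
            raise ValueError(f"stage {s + 1} interval [{lo},{hi}) is empty")
        block = daily.iloc[lo:hi]
        for t in daily.columns:
            out[f"{t}_{s + 1}"] = block[t].mean()
    # order columns type-major to match the EC matrix layout
    ordered = [f"{t}_{s + 1}" for t in daily.columns for s in range(len(bounds) - 1)]
    return pd.Series({k: out[k] for k in ordered})


def compute_sdr(series, crop_factor: float = CROP_FACTOR, clip: float = SDR_CLIP):
    """Mean clipped supply/demand ratio over the reproductive window.

    Daily demand = ``Eo x cover_green x crop_factor``; daily SDR =
    supply/demand clipped at ``clip``; zero-demand days are set to the clip
    value (the saturation the ratio would reach with no transpiration demand)
    and flagged.  Returns ``(SDR, daily SDR trace over the window)``.
    """
    lo, hi = series.window
    if lo < 0 or hi > len(series.eo) or hi <= lo:
        raise ValueError("reproductive window outside the daily series")
    eo = np.asarray(series.eo[lo:hi], float)
    cover = np.asarray(series.cover_green[lo:hi], float)
    supply = np.asarray(series.supply[lo:hi], float)
    demand = eo * cover * crop_factor
    daily = np.full(hi - lo, float(clip))
    nz = demand > 0
    daily[nz] = np.minimum(supply[nz] / demand[nz], clip)
    return float(daily.mean()), daily


def compute_hi30(series, threshold_c: float = 30.0) -> int:
    """Days in the reproductive window with tmax strictly above 30 degC."""
    lo, hi = series.window
    if lo < 0 or hi > len(series.tmax) or hi <= lo:
        raise ValueError("reproductive window outside the daily series")
    tmax = np.asarray(series.tmax[lo:hi], float)
    if np.isnan(tmax).any():
        raise ValueError("missing tmax inside the reproductive window")
    return int(np.sum(tmax > threshold_c))


def stress_flags(sdr: float, hi30: int,
                 sdr_threshold: float = SDR_THRESHOLD,
                 hi30_threshold: int = HI30_THRESHOLD):
    """Drought (``SDR <= 0.54``), heat (``HI30 > 36``), and combined flags."""
    drought = sdr <= sdr_threshold
    heat = hi30 > hi30_threshold
    return drought, heat, drought and heat


def stress_indices(series) -> StressIndices:
    sdr, _ = compute_sdr(series)
    hi30 = compute_hi30(series)
    d, h, c = stress_flags(sdr, hi30)
    return StressIndices(sdr=sdr, hi30=hi30, drought=d, heat=h, combined=c)


def tune_juvenile_gdd(simulator, observed_silking_day: float, grid):
    """Grid-search the juvenile-phase GDD requirement of the crop model.

    ``simulator(gdd) -> predicted flowering day``; the grid value minimizing
    ``|simulated - observed|`` is selected (ties go to the smaller GDD).
    Grid points where the simulator raises are skipped and logged; a best
    value at the grid boundary triggers a warning.  Returns
    ``(selected gdd, residual, log list)``.
    """
    import warnings

    grid = sorted(grid)
    if not grid:
        raise ValueError("empty GDD grid")
    log = []
    best = None
    for g in grid:
        try:
            pred = simulator(g)
        except Exception as exc:  # simulator failure: skip the point
            log.append(f"grid point {g} skipped: {exc}")
            continue
        resid = abs(pred - observed_silking_day)
        if best is None or resid < best[1] - 1e-12:
            best = (g, resid)
    if best is None:
        raise ValueError("simulator failed on every grid point")
    if best[0] in (grid[0], grid[-1]):
        warnings.warn(f"selected GDD {best[0]} lies on the grid boundary")
    return best[0], best[1], log


def _sequential_ss(y: np.ndarray, region: np.ndarray, location: np.ndarray):
    """Sequential SS for region, then location-within-region, then residual."""
    gm = y.mean()
    ss_total = np.sum((y - gm) ** 2)
    reg_mean = pd.Series(y).groupby(pd.Series(region)).transform("mean").to_numpy()
    loc_mean = pd.Series(y).groupby(pd.Series(location)).transform("mean").to_numpy()
    ss_region = np.sum((reg_mean - gm) ** 2)
    ss_location = np.sum((loc_mean - reg_mean) ** 2)
    ss_resid = np.sum((y - loc_mean) ** 2)
    return ss_region, ss_location, ss_resid, ss_total


def ec_anova(ec: pd.DataFrame, yl_meta: pd.DataFrame) -> pd.DataFrame:
    """Variance partition of each EC into region / location / year-location.

    ``yl_meta`` is indexed like ``ec`` (one row per year-location) with
    ``region`` and ``location`` columns.  Sequential sums of squares: region
    first, then location within region; the residual is the year-location
    share.  Proportions of total SS sum to 1.  Locations observed in a single
    year are allowed (they contribute no residual df) and are noted in the
    returned frame's ``attrs['single_year_locations']``.
    """
    meta = yl_meta.loc[ec.index]
    if meta["location"].nunique() < 2:
        raise ValueError("EC ANOVA needs at least two locations")
    region = meta["region"].to_numpy()
    location = meta["location"].to_numpy()
    rows = []
    for col in ec.columns:
        y = ec[col].to_numpy(dtype=float)
        ss_r, ss_l, ss_e, ss_t = _sequential_ss(y, region, location)
        if ss_t == 0:
            rows.append((col, 0.0, 0.0, 0.0))
        else:
            rows.append((col, ss_r / ss_t, ss_l / ss_t, ss_e / ss_t))
    out = pd.DataFrame(rows, columns=["ec", "region", "location", "year_location"])
    out = out.set_index("ec")
    counts = meta.groupby("location").size()
    out.attrs["single_year_locations"] = list(counts.index[counts == 1])
    return out


def ec_anova_stratified(ec: pd.DataFrame, yl_meta: pd.DataFrame) -> dict:
    """Per-region variance partition into location and year-location shares."""
    meta = yl_meta.loc[ec.index]
    out = {}
    for reg, sub in meta.groupby("region"):
        sub_ec = ec.loc[sub.index]
        location = sub["location"].to_numpy()
        rows = []
        for col in sub_ec.columns:
            y = sub_ec[col].to_numpy(dtype=float)
            gm = y.mean()
            ss_t = np.sum((y - gm) ** 2)
            loc_mean = pd.Series(y).groupby(pd.Series(location)).transform("mean").to_numpy()
            ss_l = np.sum((loc_mean - gm) ** 2)
            ss_e = np.sum((y - loc_mean) ** 2)
            if ss_t == 0:
                rows.append((col, 0.0, 0.0))
            else:
                rows.append((col, ss_l / ss_t, ss_e / ss_t))
        out[reg] = pd.DataFrame(rows, columns=["ec", "location", "year_location"]).set_index("ec")
    return out
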