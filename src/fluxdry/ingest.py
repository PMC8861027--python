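"""Reading flux CSVs and preparing daily, filtered, standardized tables.

The prep chain is: read the half-hourly FLUXNET2015-dialect table, mask by
QC flags (only measured or good-quality gap-filled data, flag 0 or 1),
aggregate daytime (07:00-19:00) half-hours to daily means, select growing
season days, standardize to z-scores, and bin days into 10x10 SWC x VPD
percentile cells with per-site decile edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (FLUXNET_COLUMNS, QC_COLUMNS, QC_FOR_VARIABLE, BinGrid,
                   SiteSeries, ZScoreParams)
from .errors import (BinningError, ContractError, DegenerateVariableError,
                     FormatError, SchemaError, UsageError)

_INV_COLUMNS = {v: k for k, v in FLUXNET_COLUMNS.items()}
_INV_QC = {v: k for k, v in QC_COLUMNS.items()}

#: columns every analysis needs; SWC layers are checked per request
_CORE_REQUIRED = ["TIMESTAMP_START", "GPP_NT_VUT_REF", "TA_F", "VPD_F", "SW_IN_F"]

#: day-selection thresholds for the growing season
TA_MIN = 15.0      # degC daily mean
VPD_MIN = 0.5      # kPa daily mean
RG_MIN = 250.0     # W m-2 daily mean
ELIGIBLE_MIN_DAYS = 300

DAY_START_H = 7
DAY_END_H = 19

PFT_BLACKLIST = ("CRO", "WET")  # croplands and wetlands excluded


def read_flux_csv(path, site_id=None, pft="unknown", zm=np.nan,
                  swc_layers=(1,)) -> SiteSeries:
    """Read one FLUXNET2015-dialect CSV into a :class:`SiteSeries`.

    ``-9999`` sentinels become NaN; timestamps are parsed from
    ``TIMESTAMP_START`` (YYYYMMDDHHMM); hourly files are accepted and
    flagged as hourly (never interpolated to half-hourly).
    """
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CORE_REQUIRED if c not in raw.columns]
    missing += [f"SWC_F_MDS_{l}" for l in swc_layers
                if f"SWC_F_MDS_{l}" not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")

    ts = pd.to_datetime(raw["TIMESTAMP_START"].astype(str), format="%Y%m%d%H%M",
                        errors="coerce")
    if ts.isna().any():
        row = int(np.argmax(ts.isna().to_numpy()))
        raise FormatError(
            f"{path.name}: unparseable TIMESTAMP_START at row {row + 2} "
            f"(value {raw['TIMESTAMP_START'].iloc[row]!r})"
        )

    data = pd.DataFrame(index=pd.DatetimeIndex(ts.to_numpy()))
    for fluxnet, internal in _INV_COLUMNS.items():
        if fluxnet in raw.columns:
            col = raw[fluxnet].to_numpy(dtype=float)
            data[internal] = np.where(col <= -9990.0, np.nan, col)
    for fluxnet, internal in _INV_QC.items():
        if fluxnet in raw.columns:
            data[internal] = raw[fluxnet].to_numpy(dtype=int)

    step = 30
    if len(data) > 1:
        step = int((data.index[1] - data.index[0]).total_seconds() // 60)
    if step not in (30, 60):
        raise FormatError(f"{path.name}: unsupported timestep {step} min")
    return SiteSeries(site_id=site_id or path.stem, pft=pft, zm=zm,
                      data=data, step_minutes=step)


def read_site_metadata(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def qc_mask(series: SiteSeries, variable: str) -> pd.Series:
    """True where the variable is usable: QC flag in {0, 1} and value present.

    Variables without a QC twin (e.g. ws, precip) are masked on presence only.
    """
    d = series.data
    if variable not in d.columns:
        raise ContractError(f"variable {variable!r} not in series")
    mask = d[variable].notna()
    qc_col = QC_FOR_VARIABLE.get(variable)
    if qc_col is not None:
        if qc_col not in d.columns:
            raise ContractError(f"QC twin {qc_col!r} missing for {variable!r}")
        mask &= d[qc_col].isin((0, 1))
    return mask


@dataclass
class DailyTable:
    """Daily daytime-mean records for one site."""

    site_id: str
    pft: str
    zm: float
    data: pd.DataFrame  # indexed by date
    min_valid_frac: float = 0.5

    @property
    def low_coverage(self) -> pd.Series:
        """Days with under min_valid_frac valid daytime half-hours (kept, flagged)."""
        return self.data["fraction_valid"] < self.min_valid_frac


_DAILY_MEAN_VARS = ["gpp_nt", "gpp_dt", "gpp_nt_25", "gpp_nt_75", "ta", "vpd",
                    "rg", "ws", "ustar", "le", "le_corr", "rn", "g_soil",
                    "swc_1", "swc_2", "swc_3", "swc_4"]


def aggregate_daytime_daily(series: SiteSeries, swc_layer: int = 1,
                            min_valid_frac: float = 0.5,
                            coverage_var: str = "gpp_nt") -> DailyTable:
    """Daytime (07:00-19:00) means per day, each variable under its own QC mask.

    Precipitation is summed over the full 24 h. ``fraction_valid`` is the
    share of daytime slots where ``coverage_var`` passes QC; days below
    ``min_valid_frac`` are retained and flagged, not dropped.
    """
    d = series.data
    minutes = d.index.hour * 60 + d.index.minute
    daytime = (minutes >= DAY_START_H * 60) & (minutes < DAY_END_H * 60)
    dates = d.index.normalize()

    out = {}
    for var in _DAILY_MEAN_VARS:
        if var not in d.columns:
            continue
        ok = qc_mask(series, var) & daytime
        vals = d[var].where(ok)
        out[var] = vals.groupby(dates).mean()
    if "precip" in d.columns:
        out["precip"] = d["precip"].groupby(dates).sum(min_count=1)

    ok_cov = qc_mask(series, coverage_var) & daytime
    n_day_slots = pd.Series(daytime.astype(int), index=d.index).groupby(dates).sum()
    n_valid = pd.Series(ok_cov.astype(int).to_numpy(), index=d.index).groupby(dates).sum()
    frac = (n_valid / n_day_slots).where(n_day_slots > 0)

    daily = pd.DataFrame(out)
    daily["fraction_valid"] = frac
    if swc_layer not in (1, 2, 3, 4):
        raise UsageError(f"swc_layer must be 1..4, got {swc_layer}")
    layer_col = f"swc_{swc_layer}"
    if layer_col not in daily.columns:
        raise SchemaError(f"site {series.site_id}: no column {layer_col}")
    daily["swc"] = daily[layer_col]
    return DailyTable(site_id=series.site_id, pft=series.pft, zm=series.zm,
                      data=daily, min_valid_frac=min_valid_frac)


@dataclass
class SeasonSelection:
    """Growing-season day subset plus the site eligibility verdict."""

    days: pd.DataFrame
    mode: str
    eligible: bool       # at least 300 selected growing-season days
    n_selected: int


def _threshold_mask(daily: pd.DataFrame) -> pd.Series:
    return (daily["ta"] > TA_MIN) & (daily["vpd"] > VPD_MIN) & (daily["rg"] > RG_MIN)


def filter_growing_season(daily: pd.DataFrame, mode: str = "threshold",
                          gpp_col: str = "gpp_nt") -> SeasonSelection:
    """Select analysis days.

    ``threshold``
        warm (Ta > 15 degC), dry-air (VPD > 0.5 kPa), bright (Rg > 250 W m-2)
        days -- the conditions under which SWC/VPD limitation dominates.
    ``peak3mo``
        the 3 consecutive calendar months (wrapping December-January) with
        maximum multi-year mean GPP; ties break to the earliest start month.
    ``deseason``
        threshold selection, with every numeric variable returned as an
        anomaly from its multi-year mean seasonal cycle smoothed by a 30-day
        moving average.
    """
    if mode not in ("threshold", "peak3mo", "deseason"):
        raise UsageError(f"unknown growing-season mode {mode!r}")
    for col in ("ta", "vpd", "rg"):
        if col not in daily.columns:
            raise ContractError(f"daily table lacks {col!r}")

    thr = _threshold_mask(daily)
    n_grow = int(thr.fillna(False).sum())
    eligible = n_grow >= ELIGIBLE_MIN_DAYS

    if mode == "threshold":
        sel = daily[thr.fillna(False)]
        return SeasonSelection(days=sel, mode=mode, eligible=eligible,
                               n_selected=len(sel))

    if mode == "peak3mo":
        monthly = daily[gpp_col].groupby(daily.index.month).mean()
        means = monthly.reindex(range(1, 13))
        best, best_val = None, -np.inf
        for start in range(1, 13):
            months = [(start - 1 + k) % 12 + 1 for k in range(3)]
            v = means.loc[months].mean()
            if np.isfinite(v) and v > best_val + 1e-12:
                best, best_val = months, v
        if best is None:
            raise ContractError("peak3mo: no months with GPP data")
        sel = daily[daily.index.month.isin(best)]
        return SeasonSelection(days=sel, mode=mode, eligible=eligible,
                               n_selected=len(sel))

    # deseason: anomalies from the smoothed multi-year mean seasonal cycle
    doy = daily.index.dayofyear.where(daily.index.dayofyear <= 365, 365)
    num = daily.select_dtypes(include=[np.number])
    cyc = num.groupby(doy).mean().reindex(range(1, 366))
    cyc = cyc.interpolate(limit_direction="both")
    wrapped = pd.concat([cyc.iloc[-15:], cyc, cyc.iloc[:15]])
    smooth = wrapped.rolling(30, center=True, min_periods=1).mean().iloc[15:-15]
    anoms = num.to_numpy() - smooth.loc[doy].to_numpy()
    out = pd.DataFrame(anoms, index=daily.index, columns=num.columns)
    sel = out[thr.fillna(False)]
    return SeasonSelection(days=sel, mode=mode, eligible=eligible,
                           n_selected=len(sel))


def zscore(days: pd.DataFrame, variables: list[str]) -> tuple[pd.DataFrame, ZScoreParams]:
    """Standardize each variable to zero mean, unit sd (n-1) over the day set."""
    means, sds = {}, {}
    out = days.copy()
    for v in variables:
        if v not in days.columns:
            raise ContractError(f"zscore: variable {v!r} not present")
        x = days[v].astype(float)
        if x.notna().sum() < 2:
            raise DegenerateVariableError(f"variable {v!r} has <2 values")
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise DegenerateVariableError(f"variable {v!r} has zero variance")
        means[v], sds[v] = mu, sd
        out[v] = (x - mu) / sd
    params = ZScoreParams(means=pd.Series(means), sds=pd.Series(sds))
    return out, params


def relative_change(x_year: float, x_ref: float) -> float:
    """Percent change of one summer mean relative to the all-summers mean."""
    if x_ref == 0:
        raise ContractError("relative_change: reference mean is zero")
    return 100.0 * (x_year - x_ref) / x_ref


def summer_relative_changes(daily: pd.DataFrame,
                            variables=("gpp_nt", "swc", "vpd")) -> pd.DataFrame:
    """Per-year June-July-August relative changes (%) against all summers."""
    jja = daily[daily.index.month.isin((6, 7, 8))]
    rows = {}
    for year, grp in jja.groupby(jja.index.year):
        rows[year] = {
            v: relative_change(grp[v].mean(), jja[v].mean()) for v in variables
        }
    return pd.DataFrame(rows).T


def assign_bins(days: pd.DataFrame, swc_col: str = "swc",
                vpd_col: str = "vpd") -> tuple[BinGrid, pd.DataFrame]:
    """Per-site 10x10 percentile binning of daily SWC and VPD.

    Decile edges are the 10th..90th percentiles (linear-interpolation
    definition) of the selected days; bins are left-closed/right-open except
    the last, so a value equal to an edge falls in the next bin. Returns the
    edges and per-day integer labels ``(i_swc, j_vpd)`` in 1..10.
    """
    if len(days) < 10:
        raise BinningError(f"need >=10 selected days to bin, got {len(days)}")
    swc = days[swc_col].to_numpy(dtype=float)
    vpd = days[vpd_col].to_numpy(dtype=float)
    if np.isnan(swc).any() or np.isnan(vpd).any():
        raise BinningError("binning variables contain missing values")
    q = np.arange(10, 100, 10)
    grid = BinGrid(swc_edges=np.percentile(swc, q), vpd_edges=np.percentile(vpd, q))
    labels = pd.DataFrame(
        {
            "i_swc": np.searchsorted(grid.swc_edges, swc, side="right") + 1,
            "j_vpd": np.searchsorted(grid.vpd_edges, vpd, side="right") + 1,
        },
        index=days.index,
    )
    return grid, labels
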