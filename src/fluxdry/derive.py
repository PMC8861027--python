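"""Daily derived biophysical quantities for one site.

Combines the inversions into the per-day table the sensitivity stage
consumes: canopy conductance Gc (Penman-Monteith inversion on rain-free
daytime half-hours), Amax (windowed light-response plateau), ci (midday
Fick's-law drawdown), Vcmax/Vcmax25 (Rubisco-limited inversion) and iWUE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import biophysics as bp
from .core import SiteSeries
from .errors import UsageError
from .lightresponse import fit_light_response_windows

RAIN_MM = 0.1        # daily precip above this excludes the day and the next
CI_RG_MIN = 500.0    # W m-2 midday radiation floor for the ci estimate
CI_H_START, CI_H_END = 11, 14


def rain_free_days(series: SiteSeries, thresh_mm: float = RAIN_MM) -> pd.Series:
    """Boolean per-date mask: False on rainy days and the day after."""
    precip = series.data["precip"].groupby(series.data.index.normalize()).sum()
    rainy = precip > thresh_mm
    blocked = rainy | rainy.shift(1, fill_value=False)
    return ~blocked


def daily_gc(series: SiteSeries, le_variant: str = "le",
             h_canopy: float | None = None) -> pd.DataFrame:
    """Daytime-mean canopy conductance (mol m-2 s-1) from the PM inversion.

    Half-hours must be rain-free, insolated (rg > 0), with positive LE and
    VPD; the per-slot inverted conductances are averaged per day. Also
    returns the count of degenerate (flagged-missing) inversions.
    """
    if le_variant not in ("le", "le_corr"):
        raise UsageError(f"le_variant must be 'le' or 'le_corr', got {le_variant!r}")
    d = series.data
    series.require_columns([le_variant, "rn", "g_soil", "ta", "vpd", "ws", "ustar", "rg"])
    if h_canopy is None:
        h_canopy = series.h_canopy_true
        if h_canopy is None:
            h_canopy = bp.site_canopy_height(series)

    dates = d.index.normalize()
    ok_day = rain_free_days(series)
    usable = (
        dates.isin(ok_day.index[ok_day])
        & (d["rg"] > 0)
        & (d[le_variant] > 0)
        & (d["vpd"] > 0.01)
        & (d["ws"] > 0)
    )
    sub = d[usable]
    ra = bp.aerodynamic_resistance(sub["ws"].to_numpy(), series.zm, h_canopy)
    gc_ms = bp.invert_penman_monteith(
        sub[le_variant].to_numpy(), sub["rn"].to_numpy(), sub["g_soil"].to_numpy(),
        sub["ta"].to_numpy(), sub["vpd"].to_numpy(), ra,
    )
    gc_mol = bp.gc_ms_to_mol(gc_ms, sub["ta"].to_numpy())
    frame = pd.DataFrame({"gc_mol": gc_mol, "ra": ra, "ta": sub["ta"].to_numpy()},
                         index=sub.index)
    n_flagged = int(np.isnan(gc_ms).sum())
    daily = frame.groupby(frame.index.normalize()).mean()
    daily.attrs["n_flagged_inversions"] = n_flagged
    return daily


def midday_ci(series: SiteSeries, gc_daily: pd.DataFrame,
              gpp_col: str = "gpp_nt", ca: float = bp.CONST.ca) -> pd.Series:
    """Midday (11:00-14:00, rg >= 500 W m-2) leaf-internal CO2 per day.

    Uses the day's mean conductance and molar aerodynamic resistance; values
    outside (Gamma*, ca) are flagged invalid (NaN).
    """
    d = series.data
    hours = d.index.hour
    mid = (hours >= CI_H_START) & (hours < CI_H_END) & (d["rg"] >= CI_RG_MIN)
    sub = d[mid]
    g = sub.groupby(sub.index.normalize()).mean()
    g = g.join(gc_daily[["gc_mol", "ra"]], how="inner")
    ra_mol = bp.resistance_to_molar(g["ra"].to_numpy(), g["ta"].to_numpy())
    ci = bp.leaf_internal_co2(g[gpp_col].to_numpy(), g["gc_mol"].to_numpy(),
                              ra_mol, ca=ca)
    ci = np.asarray(ci, dtype=float)
    gs = bp.gammastar(g["ta"].to_numpy())
    ci = np.where((ci <= gs) | (ci >= ca), np.nan, ci)
    return pd.Series(ci, index=g.index, name="ci")


def derive_daily(series: SiteSeries, le_variant: str = "le",
                 gpp_col: str = "gpp_nt", amax_mode: str = "beta0") -> pd.DataFrame:
    """Full per-day derived table: gc_mol, amax, ci, vcmax, vcmax25, iwue."""
    gc = daily_gc(series, le_variant=le_variant)
    amax_daily, _ = fit_light_response_windows(series, amax_mode=amax_mode)
    ci = midday_ci(series, gc, gpp_col=gpp_col)

    d = series.data
    minutes = d.index.hour * 60 + d.index.minute
    daytime = (minutes >= 7 * 60) & (minutes < 19 * 60)
    gpp_day = d.loc[daytime, gpp_col].groupby(d.index[daytime].normalize()).mean()

    out = pd.DataFrame(index=gc.index)
    out["gc_mol"] = gc["gc_mol"]
    out["ta_mid"] = gc["ta"]
    out = out.join(ci, how="left")
    if len(amax_daily):
        out = out.join(amax_daily[["amax"]], how="left")
    else:
        out["amax"] = np.nan
    out = out.join(gpp_day.rename("gpp_day"), how="left")

    vcmax, vcmax25 = bp.invert_vcmax(out["amax"].to_numpy(), out["ci"].to_numpy(),
                                     out["ta_mid"].to_numpy())
    out["vcmax"] = vcmax
    out["vcmax25"] = vcmax25
    out["iwue"] = bp.iwue(out["gpp_day"].to_numpy(), out["gc_mol"].to_numpy())
    return out
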