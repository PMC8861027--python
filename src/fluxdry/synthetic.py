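"""Synthetic multi-site flux-tower generator with an analytic ground truth.

The generator produces half-hourly FLUXNET2015-dialect series whose GPP
responds to soil water content (SWC), vapor pressure deficit (VPD) and
shortwave radiation (Rg) through a known, differentiable surface:

* biochemical capacity ``A*(SWC)`` is a smooth unimodal curve -- the product
  of two logistic ramps placed symmetrically about ``swc_opt`` -- that
  declines below ``swc_lo`` (drought) and above the mirror point
  ``2*swc_opt - swc_lo`` (waterlogging-like);
* a VPD multiplier ``m(VPD) = exp(-vpd_decay * max(0, VPD - vpd0))``;
* instantaneous GPP follows a rectangular-hyperbola light response with
  plateau ``A* m``:  ``GPP = A m * alpha Rg / (alpha Rg + A m)``.

Latent heat is produced by the *forward* Penman-Monteith equation from a
Medlyn-form conductance, respiration follows a Q10 law, and NEE closes the
carbon budget, so every downstream inversion has an exact round-trip oracle
at zero noise. Daily weather couples VPD and SWC negatively (dry soil,
warm/dry air) the way land-atmosphere feedbacks do at real towers.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import biophysics as bp
from .core import FLUXNET_COLUMNS, QC_COLUMNS, SiteSeries
from .errors import ContractError, ParameterError

PFT_CYCLE = ("ENF", "DBF", "GRA", "SAV", "EBF", "MF")

# daily weather-model constants (calibrated once; see docs/methods.md)
RG_MEAN = 250.0        # W m-2 seasonal daytime-mean radiation midpoint
RG_AMP = 170.0         # W m-2 seasonal amplitude (peak mid-July)
RG_PEAK_DOY = 197
TA_INTERCEPT = 2.5     # degC; Ta linear in daily Rg plus noise
TA_SLOPE = 0.055
TA_NOISE_SD = 3.0
SWC_BASE = 30.0        # % seasonal midpoint of surface SWC
SWC_AMP = 4.0          # % seasonal amplitude (wet early March, dry late Aug)
SWC_PEAK_DOY = 65
SWC_INPUT_SD = 0.6     # % white innovation of the AR(1) anomaly
SWC_RECHARGE = 0.3     # % SWC per mm precipitation anomaly
RH_BASE = 68.0         # % relative humidity model: rh = base + b_swc*(swc-28) - b_ta*(ta-12)
RH_SWC_SLOPE = 1.1
RH_TA_SLOPE = 1.6
RH_NOISE_SD = 8.0
CA_UMOL = bp.CONST.ca  # 400 umol mol-1, fixed


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth response-surface and simulation parameters.

    The defaults define the study conditions of the synthetic experiment:
    20 sites x 3 years at half-hourly step, moderate multiplicative flux
    noise, and an SWC optimum placed inside the growing-season SWC range so
    that the driest decile columns sit below it and the wettest above it.
    """

    swc_opt: float = 26.0        # % volumetric SWC at peak capacity
    swc_lo: float = 15.0         # % lower ramp midpoint (decline below)
    amax_peak: float = 30.0      # umol CO2 m-2 s-1
    vpd_decay: float = 0.15      # kPa-1
    vpd0: float = 1.0            # kPa decay onset
    alpha_true: float = 0.05     # umol CO2 per W shortwave
    g1: float = 3.0              # kPa^0.5 stomatal slope
    g0: float = 0.01             # mol m-2 s-1 residual conductance
    reco_base: float = 2.0       # umol m-2 s-1 at 15 degC
    q10: float = 2.0
    noise_sd_rel: float = 0.02   # relative (multiplicative) flux noise
    ar1_phi: float = 0.85        # daily SWC anomaly memory
    n_sites: int = 20
    n_days: int = 1095
    seed: int = 0
    swc_width: float = 12.0      # % logistic ramp width
    qc_bad_frac: float = 0.02    # fraction of QC flags >= 2
    missing_frac: float = 0.005  # fraction of missing flux values
    step_minutes: int = 30
    start: str = "2014-01-01"

    def validate(self) -> "TruthParams":
        if not self.swc_lo < self.swc_opt:
            raise ParameterError("swc_lo must be < swc_opt")
        if self.vpd_decay < 0:
            raise ParameterError("vpd_decay must be >= 0")
        if self.amax_peak <= 0:
            raise ParameterError("amax_peak must be > 0")
        if not 0 <= self.ar1_phi < 1:
            raise ParameterError("ar1_phi must be in [0, 1)")
        if self.noise_sd_rel < 0:
            raise ParameterError("noise_sd_rel must be >= 0")
        if self.swc_width <= 0:
            raise ParameterError("swc_width must be > 0")
        if self.n_days < 30:
            raise ParameterError("n_days must be >= 30")
        if self.step_minutes not in (30, 60):
            raise ParameterError("step_minutes must be 30 or 60")
        if not 0 <= self.qc_bad_frac < 1:
            raise ParameterError("qc_bad_frac must be in [0, 1)")
        return self

    def with_overrides(self, **kw) -> "TruthParams":
        known = {f.name for f in fields(self)}
        bad = set(kw) - known
        if bad:
            raise ParameterError(f"unknown TruthParams fields: {sorted(bad)}")
        return replace(self, **kw).validate()


# ------------------------------------------------------------ truth surface

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def capacity(params: TruthParams, swc):
    """Biochemical capacity A*(SWC), peaking at swc_opt with value amax_peak."""
    s = np.asarray(swc, dtype=float)
    w = params.swc_width
    hi = 2.0 * params.swc_opt - params.swc_lo  # mirror point above the optimum
    raw = _sigmoid((s - params.swc_lo) / w) * _sigmoid((hi - s) / w)
    peak = _sigmoid((params.swc_opt - params.swc_lo) / w) ** 2
    return params.amax_peak * raw / peak


def vpd_multiplier(params: TruthParams, vpd):
    """Exponential VPD down-regulation above the vpd0 onset."""
    v = np.asarray(vpd, dtype=float)
    return np.exp(-params.vpd_decay * np.maximum(0.0, v - params.vpd0))


def gpp_instant(params: TruthParams, swc, vpd, rg):
    """Instantaneous true GPP (umol m-2 s-1) at given drivers."""
    a = capacity(params, swc) * vpd_multiplier(params, vpd)
    light = params.alpha_true * np.asarray(rg, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(light + a > 0, a * light / (light + a), 0.0)
    return out


def _capacity_dswc(params: TruthParams, swc):
    """Analytic dA*/dSWC."""
    s = np.asarray(swc, dtype=float)
    w = params.swc_width
    hi = 2.0 * params.swc_opt - params.swc_lo
    u1 = _sigmoid((s - params.swc_lo) / w)
    u2 = _sigmoid((hi - s) / w)
    peak = _sigmoid((params.swc_opt - params.swc_lo) / w) ** 2
    d = (u1 * (1 - u1) / w) * u2 - u1 * (u2 * (1 - u2) / w)
    return params.amax_peak * d / peak


def gpp_partials(params: TruthParams, swc, vpd, rg):
    """Analytic (dGPP/dSWC, dGPP/dVPD) of the instantaneous surface."""
    v = np.asarray(vpd, dtype=float)
    a = capacity(params, swc) * vpd_multiplier(params, vpd)
    light = params.alpha_true * np.asarray(rg, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dg_da = np.where(light + a > 0, light**2 / (light + a) ** 2, 0.0)
    da_ds = _capacity_dswc(params, swc) * vpd_multiplier(params, vpd)
    m_prime = np.where(v > params.vpd0, -params.vpd_decay, 0.0) * vpd_multiplier(params, vpd)
    da_dv = capacity(params, swc) * m_prime
    return dg_da * da_ds, dg_da * da_dv


def true_sensitivities(params: TruthParams, swc, vpd, ta=None, rg=800.0, scale=None):
    """Pointwise true sensitivities with the reporting orientations.

    Returns ``(s_swc, s_vpd)`` where ``s_swc`` is drying-oriented (negative
    when drying reduces GPP, i.e. the negated SWC partial) and ``s_vpd``
    is the raw VPD partial (negative when rising VPD reduces GPP). ``scale``
    optionally maps to z-units as ``(sd_swc, sd_vpd, sd_gpp)``.
    """
    d_ds, d_dv = gpp_partials(params, swc, vpd, rg)
    s_swc = -d_ds
    s_vpd = d_dv
    if scale is not None:
        sd_swc, sd_vpd, sd_gpp = scale
        s_swc = s_swc * sd_swc / sd_gpp
        s_vpd = s_vpd * sd_vpd / sd_gpp
    return s_swc, s_vpd


# ------------------------------------------------------------- diurnal shapes

def _diurnal_shapes(step_minutes: int):
    """Fixed within-day shapes and their daytime (07-19 h) normalizers."""
    n = int(24 * 60 / step_minutes)
    hours = (np.arange(n) + 0.5) * step_minutes / 60.0
    daytime = (hours >= 7.0) & (hours < 19.0)
    shape_rg = np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
    shape_rg[(hours < 6.0) | (hours > 18.0)] = 0.0
    shape_vpd = np.maximum(0.15, 1.0 + 0.55 * np.cos(2 * np.pi * (hours - 15.0) / 24.0))
    ta_anom = 4.0 * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    ta_anom = ta_anom - ta_anom[daytime].mean()
    return {
        "hours": hours,
        "daytime": daytime,
        "shape_rg": shape_rg / shape_rg[daytime].mean(),
        "shape_vpd": shape_vpd / shape_vpd[daytime].mean(),
        "ta_anom": ta_anom,
    }


def seasonal_swc(doy):
    """Seasonal component of surface SWC (%): wet early spring, dry late summer."""
    return SWC_BASE + SWC_AMP * np.cos(2 * np.pi * (np.asarray(doy, dtype=float) - SWC_PEAK_DOY) / 365.0)


# --------------------------------------------------------------- meteorology

def simulate_meteorology(params: TruthParams, site_index: int) -> SiteSeries:
    """Generate driver columns (ta, vpd, swc_1..4, rg, ws, ustar, precip).

    Daily SWC is a seasonal sinusoid plus a mean-reverting AR(1) anomaly fed
    by precipitation recharge; relative humidity is built to fall when soil
    dries and air warms, so daily VPD and SWC correlate negatively. The
    half-hourly downscaling uses fixed diurnal shapes normalized so the
    07-19 h daytime mean of each driver equals its daily value.
    """
    params.validate()
    rng = np.random.default_rng((params.seed, site_index))
    nd = params.n_days
    dates = pd.date_range(params.start, periods=nd, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)

    # per-site geometry (drawn first; keep the draw order stable)
    h_canopy = float(rng.uniform(8.0, 22.0))
    zm = round(2.0 * h_canopy, 1)
    pft = PFT_CYCLE[site_index % len(PFT_CYCLE)]

    # daily weather
    cloud = rng.beta(2.0, 4.0, nd)
    rg_d = (RG_MEAN + RG_AMP * np.cos(2 * np.pi * (doy - RG_PEAK_DOY) / 365.0)) * (1.0 - 0.65 * cloud)
    rg_d = np.clip(rg_d, 5.0, None)
    precip = np.where(cloud > 0.45, rng.gamma(1.5, 4.0, nd), 0.0)
    ta_d = TA_INTERCEPT + TA_SLOPE * rg_d + rng.normal(0.0, TA_NOISE_SD, nd)

    innov = SWC_RECHARGE * (precip - precip.mean()) + rng.normal(0.0, SWC_INPUT_SD, nd)
    anom = lfilter([1.0], [1.0, -params.ar1_phi], innov)
    swc1_d = np.clip(seasonal_swc(doy) + anom, 2.0, 60.0)

    rh = RH_BASE + RH_SWC_SLOPE * (swc1_d - 28.0) - RH_TA_SLOPE * (ta_d - 12.0)
    rh = np.clip(rh + rng.normal(0.0, RH_NOISE_SD, nd), 25.0, 98.0)
    vpd_d = np.maximum(0.05, bp.esat(ta_d) * (1.0 - rh / 100.0))

    ws_d = 0.8 + rng.gamma(4.0, 0.6, nd)

    # deeper layers: lagged, smoothed copies of the surface layer
    s1 = pd.Series(swc1_d)
    deep = {
        "swc_2": s1.rolling(7, min_periods=1).mean().shift(3),
        "swc_3": s1.rolling(15, min_periods=1).mean().shift(7),
        "swc_4": s1.rolling(31, min_periods=1).mean().shift(15),
    }
    for k in deep:
        deep[k] = deep[k].bfill().to_numpy()

    # half-hourly downscaling
    sh = _diurnal_shapes(params.step_minutes)
    n_slot = sh["hours"].size
    idx = pd.date_range(params.start, periods=nd * n_slot,
                        freq=f"{params.step_minutes}min")

    def tile_daily(x):
        return np.repeat(np.asarray(x, dtype=float), n_slot)

    rg_hh = (rg_d[:, None] * sh["shape_rg"][None, :]).ravel()
    vpd_hh = (vpd_d[:, None] * sh["shape_vpd"][None, :]).ravel()
    ta_hh = (ta_d[:, None] + sh["ta_anom"][None, :]).ravel()
    ws_hh = (ws_d[:, None] * (0.85 + 0.3 * sh["shape_rg"][None, :] / sh["shape_rg"].max())).ravel()
    # friction velocity consistent with the canopy-height relation, so the
    # per-site height (and hence ra) is exactly recoverable downstream
    ws_over_ustar = np.log(10.0 * (zm / h_canopy - 0.6)) / bp.CONST.k_vk
    ustar_hh = ws_hh / ws_over_ustar

    precip_hh = np.zeros((nd, n_slot))
    rain_slots = (sh["hours"] >= 2.0) & (sh["hours"] < 3.0)
    precip_hh[:, rain_slots] = precip[:, None] / rain_slots.sum()

    data = pd.DataFrame(
        {
            "ta": ta_hh,
            "vpd": vpd_hh,
            "rg": rg_hh,
            "ws": ws_hh,
            "ustar": ustar_hh,
            "precip": precip_hh.ravel(),
            "swc_1": tile_daily(swc1_d),
            "swc_2": tile_daily(deep["swc_2"]),
            "swc_3": tile_daily(deep["swc_3"]),
            "swc_4": tile_daily(deep["swc_4"]),
        },
        index=idx,
    )
    return SiteSeries(
        site_id=f"SYN-{site_index:03d}", pft=pft, zm=zm, data=data,
        step_minutes=params.step_minutes, truth=params,
        h_canopy_true=h_canopy, site_index=site_index,
    )


# -------------------------------------------------------------------- fluxes

_QC_VARS = list(QC_COLUMNS)


def simulate_fluxes(met: SiteSeries, params: TruthParams) -> SiteSeries:
    """Populate fluxes, conductance-consistent LE, QC flags and noise."""
    params.validate()
    needed = ["ta", "vpd", "rg", "ws", "ustar", "precip", "swc_1"]
    missing = [c for c in needed if c not in met.data.columns]
    if missing:
        raise ContractError(f"simulate_fluxes: met series lacks drivers {missing}")

    rng = np.random.default_rng((params.seed, met.site_index, 1))
    d = met.data.copy()
    n = len(d)

    gpp_true = gpp_instant(params, d["swc_1"].to_numpy(), d["vpd"].to_numpy(), d["rg"].to_numpy())
    reco = params.reco_base * params.q10 ** ((d["ta"].to_numpy() - 15.0) / 10.0)

    fs = 0.3 + 0.7 * _sigmoid((d["swc_1"].to_numpy() - params.swc_lo) / params.swc_width)
    vpd_safe = np.maximum(d["vpd"].to_numpy(), 0.05)
    gc_mol = params.g0 + fs * 1.6 * (1.0 + params.g1 / np.sqrt(vpd_safe)) * gpp_true / CA_UMOL
    gc_ms = gc_mol / bp.molar_density(d["ta"].to_numpy())

    ra = bp.aerodynamic_resistance(d["ws"].to_numpy(), met.zm, met.h_canopy_true)
    rn = 0.62 * d["rg"].to_numpy() - 25.0
    g_soil = 0.12 * rn
    le_true = bp.penman_monteith_forward(gc_ms, ra, rn - g_soil, d["ta"].to_numpy(), d["vpd"].to_numpy())

    s = params.noise_sd_rel

    def noisy(x):
        return x * (1.0 + s * rng.normal(0.0, 1.0, n))

    d["nee"] = noisy(reco - gpp_true)
    d["gpp_nt"] = noisy(gpp_true)
    d["gpp_dt"] = noisy(gpp_true)
    d["gpp_nt_25"] = d["gpp_nt"] * 0.88
    d["gpp_nt_75"] = d["gpp_nt"] * 1.12
    d["le"] = noisy(le_true)
    d["le_corr"] = noisy(1.12 * le_true)
    d["h_flux"] = noisy(rn - g_soil - le_true)
    d["rn"] = rn
    d["g_soil"] = g_soil
    # internal truth columns (not part of the written dialect)
    d["gpp_true"] = gpp_true
    d["reco_true"] = reco
    d["gc_true_mol"] = gc_mol
    d["le_true"] = le_true

    p0 = max(0.0, 1.0 - 0.10 - params.qc_bad_frac)
    for qc in _QC_VARS:
        u = rng.random(n)
        d[qc] = np.select([u < p0, u < p0 + 0.10], [0, 1], default=2).astype(int)
    if params.missing_frac > 0:
        for col in ("nee", "gpp_nt", "gpp_dt", "le"):
            gap = rng.random(n) < params.missing_frac
            d.loc[gap, col] = np.nan
    d.loc[d["nee"].isna(), ["gpp_nt_25", "gpp_nt_75"]] = np.nan

    return SiteSeries(
        site_id=met.site_id, pft=met.pft, zm=met.zm, data=d,
        step_minutes=met.step_minutes, truth=params,
        h_canopy_true=met.h_canopy_true, site_index=met.site_index,
    )


def simulate_site(params: TruthParams, site_index: int) -> SiteSeries:
    """Drivers plus fluxes for one site."""
    return simulate_fluxes(simulate_meteorology(params, site_index), params)


def simulate_sites(params: TruthParams) -> list[SiteSeries]:
    return [simulate_site(params, i) for i in range(params.n_sites)]


# ----------------------------------------------------------- daily-scale truth

def daily_gpp_truth(params: TruthParams, swc, vpd_day, rg_day):
    """True daytime-mean GPP given daily drivers.

    Rebuilds the deterministic diurnal profiles used by the generator's
    downscaling (whose daytime means equal the daily values) and averages
    instantaneous GPP over the 07-19 h window. This is the forward model on
    which the perturbation-sensitivity oracle operates.
    """
    sh = _diurnal_shapes(params.step_minutes)
    day = sh["daytime"]
    swc = np.atleast_1d(np.asarray(swc, dtype=float))
    vpd_day = np.atleast_1d(np.asarray(vpd_day, dtype=float))
    rg_day = np.atleast_1d(np.asarray(rg_day, dtype=float))
    rg_hh = rg_day[:, None] * sh["shape_rg"][None, day]
    vpd_hh = vpd_day[:, None] * sh["shape_vpd"][None, day]
    gpp = gpp_instant(params, swc[:, None], vpd_hh, rg_hh)
    out = gpp.mean(axis=1)
    return out if out.size > 1 else float(out[0])


def true_perturbation_sensitivities(params: TruthParams, days: pd.DataFrame,
                                    sd_swc: float, sd_vpd: float, sd_gpp: float,
                                    swc_col="swc", vpd_col="vpd", rg_col="rg") -> pd.DataFrame:
    """Per-day oracle matching the ANN perturbation statistic.

    Applies the same finite one-standard-deviation perturbations the ANN
    analysis uses (SWC by -1 sd, drying orientation; VPD by +1 sd) to the
    true daily forward model and standardizes by the response sd.
    """
    swc = days[swc_col].to_numpy(dtype=float)
    vpd = days[vpd_col].to_numpy(dtype=float)
    rg = days[rg_col].to_numpy(dtype=float)
    base = daily_gpp_truth(params, swc, vpd, rg)
    s_swc = (daily_gpp_truth(params, swc - sd_swc, vpd, rg) - base) / sd_gpp
    s_vpd = (daily_gpp_truth(params, swc, vpd + sd_vpd, rg) - base) / sd_gpp
    return pd.DataFrame({"s_swc": s_swc, "s_vpd": s_vpd}, index=days.index)


def decouple_swc(series: SiteSeries, params: TruthParams, seed: int) -> SiteSeries:
    """Replace SWC with a weather-independent series (null constructions).

    Draws a fresh seasonal + AR(1) soil-moisture trajectory from its own
    stream, uncorrelated with the site's precipitation, radiation and VPD.
    Intended for runs whose capacity response is flat in SWC (so the fluxes
    do not depend on SWC); it breaks the SWC-weather covariation that would
    otherwise leak radiation or VPD signal into SWC-conditioned contrasts.
    """
    rng = np.random.default_rng((seed, series.site_index, 99))
    d = series.data.copy()
    dates = d.index.normalize().unique()
    nd = len(dates)
    # no seasonal component: a seasonal SWC would re-import the radiation
    # and VPD annual cycles into SWC-conditioned contrasts
    innov = rng.normal(0.0, 1.2, nd)
    anom = lfilter([1.0], [1.0, -params.ar1_phi], innov)
    swc = np.clip(SWC_BASE + anom, 2.0, 60.0)
    per_day = pd.Series(swc, index=dates)
    d["swc_1"] = per_day.reindex(d.index.normalize()).to_numpy()
    s1 = pd.Series(swc)
    for col, (win, lag) in {"swc_2": (7, 3), "swc_3": (15, 7), "swc_4": (31, 15)}.items():
        deep = s1.rolling(win, min_periods=1).mean().shift(lag).bfill()
        d[col] = pd.Series(deep.to_numpy(), index=dates).reindex(d.index.normalize()).to_numpy()
    return SiteSeries(site_id=series.site_id, pft=series.pft, zm=series.zm,
                      data=d, step_minutes=series.step_minutes, truth=series.truth,
                      h_canopy_true=series.h_canopy_true, site_index=series.site_index)


# ------------------------------------------------------------------- writers

def _float_repr(v) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return np.format_float_positional(v, unique=True, trim="0")


def write_fluxnet_csv(series: SiteSeries, path) -> Path:
    """Write one site to a FLUXNET2015-dialect CSV (-9999 sentinel, no quoting)."""
    path = Path(path)
    d = series.data
    out = pd.DataFrame()
    out["TIMESTAMP_START"] = d.index.strftime("%Y%m%d%H%M")
    for internal, fluxnet in FLUXNET_COLUMNS.items():
        if internal in d.columns:
            out[fluxnet] = d[internal].to_numpy()
    for internal, fluxnet in QC_COLUMNS.items():
        if internal in d.columns:
            out[fluxnet] = d[internal].to_numpy()
    out.to_csv(path, index=False, na_rep="-9999", float_format=_float_repr)
    return path


def write_site_metadata(sites: list[SiteSeries], path) -> Path:
    """Site metadata YAML (site_id, pft, zm) consumed by the prep stage."""
    import yaml

    meta = {
        s.site_id: {"pft": s.pft, "zm": float(s.zm)}
        for s in sites
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def simulate_model_daily(params: TruthParams, site_index: int,
                         gpp_noise_rel: float = 0.05) -> pd.DataFrame:
    """Daily "model output" series (gpp, tas, rsds, mrsos, vpd).

    Emulates an ESM's daily diagnostics at a site location: daily drivers
    from the same weather model, GPP from the true daily forward surface
    plus small relative noise.
    """
    met = simulate_meteorology(params, site_index)
    d = met.data
    day_mask = (d.index.hour * 60 + d.index.minute >= 7 * 60) & (
        d.index.hour * 60 + d.index.minute < 19 * 60
    )
    day = d[day_mask].groupby(d.index[day_mask].normalize()).mean()
    out = pd.DataFrame(index=day.index)
    out["tas"] = day["ta"]
    out["rsds"] = day["rg"]
    out["mrsos"] = day["swc_1"]
    out["vpd"] = day["vpd"]
    gpp = daily_gpp_truth(params, out["mrsos"].to_numpy(), out["vpd"].to_numpy(),
                          out["rsds"].to_numpy())
    rng = np.random.default_rng((params.seed, site_index, 2))
    out["gpp"] = np.atleast_1d(gpp) * (1.0 + gpp_noise_rel * rng.normal(0.0, 1.0, len(out)))
    return out


def write_model_daily_csv(df: pd.DataFrame, path) -> Path:
    """Write the daily ESM-style table (TIMESTAMP, GPP, TAS, RSDS, MRSOS, VPD)."""
    out = pd.DataFrame()
    out["TIMESTAMP"] = df.index.strftime("%Y%m%d")
    for col, name in [("gpp", "GPP"), ("tas", "TAS"), ("rsds", "RSDS"),
                      ("mrsos", "MRSOS"), ("vpd", "VPD")]:
        out[name] = df[col].to_numpy()
    path = Path(path)
    out.to_csv(path, index=False, na_rep="-9999", float_format=_float_repr)
    return path


def read_model_daily_csv(path) -> pd.DataFrame:
    """Read the daily model-output dialect back to lower-case columns."""
    from .errors import SchemaError

    raw = pd.read_csv(path, float_precision="round_trip")
    need = ["TIMESTAMP", "GPP", "TAS", "RSDS", "MRSOS", "VPD"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise SchemaError(f"model daily table missing columns {missing}")
    idx = pd.to_datetime(raw["TIMESTAMP"].astype(str), format="%Y%m%d")
    df = pd.DataFrame(
        {
            "gpp": raw["GPP"].to_numpy(dtype=float),
            "tas": raw["TAS"].to_numpy(dtype=float),
            "rsds": raw["RSDS"].to_numpy(dtype=float),
            "mrsos": raw["MRSOS"].to_numpy(dtype=float),
            "vpd": raw["VPD"].to_numpy(dtype=float),
        },
        index=idx,
    )
    df = df.mask(df <= -9990)
    return df
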