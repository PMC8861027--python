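"""Windowed light-response-curve fits yielding daily Amax.

Net CO2 flux Fc (NEE sign convention: uptake negative) is fitted within short
2-14 day windows with a rectangular hyperbola whose plateau decays
exponentially with VPD above a 1 kPa onset:

    Fc = gamma_resp - alpha * beta(VPD) * Rg / (alpha * Rg + beta(VPD))
    beta(VPD) = beta0 * exp(-k * (VPD - VPD0))   for VPD > VPD0, else beta0

Every day inside a window shares one Amax; the reported Amax is beta0, the
saturating capacity at VPD <= VPD0 (the VPD-uncorrected plateau). The
alternative convention beta(ambient VPD) is exposed as ``amax_ambient``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .biophysics import CONST
from .errors import ContractError

VPD0 = CONST.vpd0


@dataclass
class LRCParams:
    """Fitted light-response parameters for one time window."""

    alpha: float          # canopy quantum yield, umol CO2 per W
    beta0: float          # plateau capacity at VPD <= VPD0, umol m-2 s-1
    k_vpd: float          # kPa-1 exponential VPD decay of the plateau
    gamma_resp: float     # window ecosystem respiration, umol m-2 s-1
    start: object = None  # window first date
    end: object = None    # window last date (inclusive)
    n: int = 0
    rmse: float = np.nan
    k_unidentified: bool = False
    at_bound: bool = False
    converged: bool = True

    def beta(self, vpd):
        """Plateau at ambient VPD per the exponential decay law."""
        v = np.asarray(vpd, dtype=float)
        return self.beta0 * np.exp(-self.k_vpd * np.maximum(0.0, v - VPD0))


def lrc_nee(rg, vpd, alpha, beta0, k_vpd, gamma_resp):
    """Model NEE for given drivers and parameters (uptake negative)."""
    rg = np.asarray(rg, dtype=float)
    beta = beta0 * np.exp(-k_vpd * np.maximum(0.0, np.asarray(vpd, dtype=float) - VPD0))
    with np.errstate(invalid="ignore", divide="ignore"):
        uptake = np.where(alpha * rg + beta > 0, alpha * beta * rg / (alpha * rg + beta), 0.0)
    return gamma_resp - uptake


_BOUNDS = ([1e-5, 0.05, 0.0, -50.0], [2.0, 500.0, 5.0, 50.0])
_P0 = (0.03, 20.0, 0.2, 2.0)


def fit_light_response(nee, rg, vpd, start=None, end=None) -> Optional[LRCParams]:
    """Nonlinear least-squares fit of one window; None if it cannot converge.

    When the window never exceeds VPD0 the decay rate k is unidentifiable;
    it is fixed at 0 and flagged.
    """
    nee = np.asarray(nee, dtype=float)
    rg = np.asarray(rg, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    ok = np.isfinite(nee) & np.isfinite(rg) & np.isfinite(vpd)
    nee, rg, vpd = nee[ok], rg[ok], vpd[ok]
    if nee.size < 8:
        return None
    fix_k = np.nanmax(vpd) <= VPD0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            if fix_k:
                def model3(x, alpha, beta0, gamma_resp):
                    return lrc_nee(x[0], x[1], alpha, beta0, 0.0, gamma_resp)

                p0 = (_P0[0], _P0[1], _P0[3])
                lo = [_BOUNDS[0][i] for i in (0, 1, 3)]
                hi = [_BOUNDS[1][i] for i in (0, 1, 3)]
                popt, _ = curve_fit(model3, np.vstack([rg, vpd]), nee, p0=p0,
                                    bounds=(lo, hi), maxfev=5000)
                alpha, beta0, gamma_resp = popt
                k_vpd = 0.0
            else:
                def model4(x, alpha, beta0, k_vpd, gamma_resp):
                    return lrc_nee(x[0], x[1], alpha, beta0, k_vpd, gamma_resp)

                popt, _ = curve_fit(model4, np.vstack([rg, vpd]), nee, p0=_P0,
                                    bounds=_BOUNDS, maxfev=5000)
                alpha, beta0, k_vpd, gamma_resp = popt
    except RuntimeError:
        return None
    resid = nee - lrc_nee(rg, vpd, alpha, beta0, k_vpd, gamma_resp)
    at_bound = bool(
        np.isclose(alpha, _BOUNDS[0][0]) or np.isclose(alpha, _BOUNDS[1][0])
        or np.isclose(beta0, _BOUNDS[0][1]) or np.isclose(beta0, _BOUNDS[1][1])
        or (not fix_k and np.isclose(k_vpd, _BOUNDS[1][2]))
    )
    return LRCParams(
        alpha=float(alpha), beta0=float(beta0), k_vpd=float(k_vpd),
        gamma_resp=float(gamma_resp), start=start, end=end, n=int(nee.size),
        rmse=float(np.sqrt(np.mean(resid**2))), k_unidentified=fix_k,
        at_bound=at_bound,
    )


def _window_ok(rg: np.ndarray, n_min: int, rg_ratio_min: float) -> bool:
    pos = rg[np.isfinite(rg) & (rg > 0)]
    if rg.size < n_min or pos.size == 0:
        return False
    return bool(pos.max() / pos.min() >= rg_ratio_min)


def fit_light_response_windows(series, n_min=30, rg_ratio_min=5.0,
                               amax_mode="beta0") -> tuple[pd.DataFrame, list[LRCParams]]:
    """Greedy windowing over a site series: daily Amax plus window fits.

    Windows start at 2 days and extend up to 14 until at least ``n_min``
    non-gap-filled Fc half-hours spanning a sufficient Rg range are present;
    the next window starts the day after the previous one ends. Only
    measured records (QC flag 0) enter the fit.

    Returns a daily frame (date, amax, amax_ambient, window id, diagnostics)
    and the list of per-window fits.
    """
    if amax_mode not in ("beta0", "ambient"):
        raise ContractError(f"unknown amax_mode {amax_mode!r}")
    d = series.data
    series.require_columns(["nee", "rg", "vpd", "qc_nee"])
    measured = d[(d["qc_nee"] == 0) & d["nee"].notna() & d["rg"].notna() & d["vpd"].notna()]
    dates = pd.Index(sorted(d.index.normalize().unique()))
    by_day = dict(tuple(measured.groupby(measured.index.normalize())))

    fits: list[LRCParams] = []
    rows = []
    i = 0
    win_id = 0
    while i < len(dates):
        fit = None
        used_len = None
        for length in range(2, 15):
            if i + length > len(dates):
                length = len(dates) - i
            chunk = pd.concat(
                [by_day[dt] for dt in dates[i:i + length] if dt in by_day],
                axis=0,
            ) if any(dt in by_day for dt in dates[i:i + length]) else pd.DataFrame()
            if len(chunk) and _window_ok(chunk["rg"].to_numpy(), n_min, rg_ratio_min):
                fit = fit_light_response(
                    chunk["nee"].to_numpy(), chunk["rg"].to_numpy(),
                    chunk["vpd"].to_numpy(),
                    start=dates[i], end=dates[min(i + length, len(dates)) - 1],
                )
                used_len = min(length, len(dates) - i)
                if fit is not None:
                    break
            if i + length >= len(dates):
                break
        if used_len is None:
            used_len = min(14, len(dates) - i)
        if fit is not None:
            fits.append(fit)
            for dt in dates[i:i + used_len]:
                day = d[d.index.normalize() == dt]
                vpd_day = day.loc[day["rg"] > 0, "vpd"].mean()
                amax = fit.beta0 if amax_mode == "beta0" else float(fit.beta(vpd_day))
                rows.append({
                    "date": dt, "amax": amax,
                    "amax_ambient": float(fit.beta(vpd_day)) if np.isfinite(vpd_day) else np.nan,
                    "window": win_id, "rmse": fit.rmse,
                    "k_unidentified": fit.k_unidentified, "at_bound": fit.at_bound,
                })
        win_id += 1
        i += used_len
    daily = pd.DataFrame(rows)
    if len(daily):
        daily = daily.set_index("date")
    return daily, fits
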