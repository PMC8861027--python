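"""Conditional extreme-bin decomposition of SWC and VPD limitation.

Within each decile of one driver (the conditioning variable), the mean
response in the highest populated decile of the other driver is compared
with the lowest populated one; averaging those contrasts over conditioning
deciles isolates each driver's effect from their covariation:

* dGPP(VPD|SWC): high-VPD minus low-VPD response inside SWC deciles
  (negative when rising VPD limits GPP);
* dGPP(SWC|VPD): low-SWC minus high-SWC response inside VPD deciles
  (negative when drying limits GPP).

Repeating the contrast on GPP_I = GPP/Rg (re-standardized) removes the
radiation covariation that otherwise inflates both apparent roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, UsageError
from .ingest import zscore


@dataclass
class ConditionalDelta:
    """One conditional contrast: the site scalar and its per-bin vector."""

    value: float
    per_bin: pd.Series = field(default_factory=pd.Series)  # conditioning decile -> contrast
    driver: str = ""
    n_bins_used: int = 0


def normalize_by_radiation(days: pd.DataFrame, gpp_col: str = "gpp_nt",
                           rg_col: str = "rg") -> tuple[pd.Series, int]:
    """GPP_I: per-day GPP/Rg re-standardized to z-scores over the day set.

    Days with nonpositive radiation are dropped (their count is returned).
    """
    ok = days[rg_col] > 0
    n_dropped = int((~ok.fillna(False)).sum())
    ratio = (days.loc[ok, gpp_col] / days.loc[ok, rg_col]).to_frame("gpp_i")
    z, _ = zscore(ratio, ["gpp_i"])
    return z["gpp_i"], n_dropped


def delta_conditional(days: pd.DataFrame, labels: pd.DataFrame, response: str,
                      driver: str, min_cell: int = 3) -> ConditionalDelta:
    """Extreme-decile contrast of ``response`` in ``driver`` conditioned on the other.

    ``driver="vpd"`` contrasts the highest vs lowest populated VPD decile
    within each SWC decile; ``driver="swc"`` contrasts low vs high SWC
    within each VPD decile (so that limitation is negative in both cases).
    A conditioning decile qualifies when two distinct driver deciles hold at
    least ``min_cell`` days each; the site value averages the qualifying
    contrasts.
    """
    if driver not in ("vpd", "swc"):
        raise UsageError(f"driver must be 'vpd' or 'swc', got {driver!r}")
    if response not in days.columns:
        raise ContractError(f"response {response!r} not in day table")
    cond_col, drv_col = ("i_swc", "j_vpd") if driver == "vpd" else ("j_vpd", "i_swc")

    joined = pd.DataFrame({"resp": days[response]}).join(labels).dropna(subset=["resp"])
    contrasts = {}
    for cond, grp in joined.groupby(cond_col):
        counts = grp.groupby(drv_col)["resp"].count()
        populated = counts[counts >= min_cell].index.to_numpy()
        if len(populated) < 2:
            continue
        lo_bin, hi_bin = populated.min(), populated.max()
        hi = grp.loc[grp[drv_col] == hi_bin, "resp"].mean()
        lo = grp.loc[grp[drv_col] == lo_bin, "resp"].mean()
        # VPD: high minus low; SWC: low minus high (drying orientation)
        contrasts[cond] = (hi - lo) if driver == "vpd" else (lo - hi)
    if not contrasts:
        return ConditionalDelta(value=np.nan, per_bin=pd.Series(dtype=float),
                                driver=driver, n_bins_used=0)
    per_bin = pd.Series(contrasts).sort_index()
    return ConditionalDelta(value=float(per_bin.mean()), per_bin=per_bin,
                            driver=driver, n_bins_used=len(per_bin))


def site_decomposition(days_z: pd.DataFrame, days_raw: pd.DataFrame,
                       labels: pd.DataFrame, gpp_col: str = "gpp_nt",
                       min_cell: int = 3) -> dict:
    """All four site-level terms: dGPP and dGPP_I, each for VPD|SWC and SWC|VPD.

    ``days_z`` is the z-scored selected-day table (contrasted directly);
    ``days_raw`` holds the unstandardized GPP and radiation from which the
    GPP_I ratio is formed before its own standardization.
    """
    out = {
        "dgpp_vpd_given_swc": delta_conditional(days_z, labels, gpp_col, "vpd", min_cell).value,
        "dgpp_swc_given_vpd": delta_conditional(days_z, labels, gpp_col, "swc", min_cell).value,
    }
    gpp_i, _ = normalize_by_radiation(days_raw, gpp_col, "rg")
    days_i = pd.DataFrame({"gpp_i": gpp_i})
    out["dgpp_i_vpd_given_swc"] = delta_conditional(days_i, labels, "gpp_i", "vpd", min_cell).value
    out["dgpp_i_swc_given_vpd"] = delta_conditional(days_i, labels, "gpp_i", "swc", min_cell).value
    return out


def decomposition_table(per_site: dict[str, dict]) -> pd.DataFrame:
    """Long box-plot-ready table: one row per (site, term)."""
    rows = []
    for site, terms in per_site.items():
        for term, value in terms.items():
            rows.append({"site": site, "term": term, "value": value})
    return pd.DataFrame(rows)
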