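"""Shared containers and the FLUXNET2015 CSV dialect.

A half-hourly tower record is one row of a :class:`pandas.DataFrame`; the
internal (lower-case) column names map 1:1 onto the FLUXNET2015/ICOS column
dialect below. Missing values are native ``NaN`` in memory and the ``-9999``
sentinel on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ContractError

#: internal name -> FLUXNET2015 column name
FLUXNET_COLUMNS: dict[str, str] = {
    "nee": "NEE_VUT_REF",
    "gpp_nt": "GPP_NT_VUT_REF",
    "gpp_dt": "GPP_DT_VUT_REF",
    "gpp_nt_25": "GPP_NT_VUT_25",
    "gpp_nt_75": "GPP_NT_VUT_75",
    "le": "LE_F_MDS",
    "le_corr": "LE_CORR",
    "h_flux": "H_F_MDS",
    "rn": "NETRAD",
    "g_soil": "G_F_MDS",
    "ta": "TA_F",
    "vpd": "VPD_F",
    "swc_1": "SWC_F_MDS_1",
    "swc_2": "SWC_F_MDS_2",
    "swc_3": "SWC_F_MDS_3",
    "swc_4": "SWC_F_MDS_4",
    "rg": "SW_IN_F",
    "ws": "WS_F",
    "ustar": "USTAR",
    "precip": "P_F",
}

#: gap-filled variables carrying a *_QC twin (internal qc column -> FLUXNET name)
QC_COLUMNS: dict[str, str] = {
    "qc_nee": "NEE_VUT_REF_QC",
    "qc_le": "LE_F_MDS_QC",
    "qc_h": "H_F_MDS_QC",
    "qc_ta": "TA_F_QC",
    "qc_vpd": "VPD_F_QC",
    "qc_swc_1": "SWC_F_MDS_1_QC",
    "qc_swc_2": "SWC_F_MDS_2_QC",
    "qc_swc_3": "SWC_F_MDS_3_QC",
    "qc_swc_4": "SWC_F_MDS_4_QC",
    "qc_rg": "SW_IN_F_QC",
}

#: which QC twin governs each data variable (GPP variants inherit the NEE flag)
QC_FOR_VARIABLE: dict[str, str] = {
    "nee": "qc_nee",
    "gpp_nt": "qc_nee",
    "gpp_dt": "qc_nee",
    "gpp_nt_25": "qc_nee",
    "gpp_nt_75": "qc_nee",
    "le": "qc_le",
    "le_corr": "qc_le",
    "h_flux": "qc_h",
    "ta": "qc_ta",
    "vpd": "qc_vpd",
    "swc_1": "qc_swc_1",
    "swc_2": "qc_swc_2",
    "swc_3": "qc_swc_3",
    "swc_4": "qc_swc_4",
    "rg": "qc_rg",
}

MISSING_SENTINEL = -9999


@dataclass
class SiteSeries:
    """An ordered per-site collection of half-hourly (or hourly) records.

    Attributes
    ----------
    site_id:
        Short site identifier, e.g. ``"SYN-003"``.
    pft:
        Plant functional type label (grouping only; croplands/wetlands can be
        blacklisted at the prep stage).
    zm:
        Flux measurement height above ground (m).
    data:
        DataFrame indexed by timestamp with the internal columns of
        :data:`FLUXNET_COLUMNS` / :data:`QC_COLUMNS` (drivers only until
        fluxes are simulated or read).
    truth:
        Ground-truth generator parameters when the series is synthetic.
    """

    site_id: str
    pft: str
    zm: float
    data: pd.DataFrame
    step_minutes: int = 30
    truth: Optional[object] = None
    h_canopy_true: Optional[float] = None
    site_index: int = 0

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) > 1:
            steps = np.diff(idx.view("int64"))
            if not (steps > 0).all():
                raise ContractError("timestamps must be strictly increasing")
            if len(set(steps)) != 1:
                raise ContractError("timestamps must have a fixed step")

    @property
    def is_hourly(self) -> bool:
        return self.step_minutes == 60

    def require_columns(self, columns: list[str]) -> None:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise ContractError(
                f"site {self.site_id}: missing required columns {missing}"
            )


@dataclass
class ZScoreParams:
    """Per-variable mean/sd over a selected day set (sd with n-1 denominator)."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for v in self.means.index:
            out[v] = (df[v] - self.means[v]) / self.sds[v]
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for v in self.means.index:
            out[v] = df[v] * self.sds[v] + self.means[v]
        return out


@dataclass
class BinGrid:
    """Per-site decile edges for SWC and VPD (10th..90th percentile values)."""

    swc_edges: np.ndarray = field(default_factory=lambda: np.empty(9))
    vpd_edges: np.ndarray = field(default_factory=lambda: np.empty(9))

    def __post_init__(self) -> None:
        for name in ("swc_edges", "vpd_edges"):
            e = np.asarray(getattr(self, name), dtype=float)
            if e.shape != (9,) or np.any(np.diff(e) < 0):
                raise ContractError(f"{name} must be 9 nondecreasing percentile values")
            setattr(self, name, e)
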