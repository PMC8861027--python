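"""Standardized multiple regression of daily GPP anomalies.

Per site, z-scored daily GPP is regressed on z-scored SWC, VPD, their
product, air temperature and radiation by ordinary least squares:

    GPP = b1*SWC + b2*VPD + b3*SWC*VPD + b4*Ta + b5*Rg + b + eps

Coefficients are stored raw; the reporting layer flips the SWC slope to the
drying orientation (negative when drying reduces GPP) and leaves the VPD
slope in the increasing orientation, so both limitation terms plot negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, ContractError, InsufficientReplicationError
from .ingest import zscore

PREDICTORS = ["swc", "vpd", "swc_x_vpd", "ta", "rg"]


@dataclass
class LinearFit:
    """OLS fit of one site: raw standardized coefficients and diagnostics."""

    beta: np.ndarray          # raw coefficients, order = PREDICTORS
    intercept: float
    se: np.ndarray            # per-coefficient standard errors
    pvalues: np.ndarray
    resid_sd: float
    n: int
    site_id: str = ""

    @property
    def swc_slope_drying(self) -> float:
        """SWC slope per one-sd *reduction* of SWC (sign-flipped raw beta1)."""
        return -float(self.beta[0])

    @property
    def vpd_slope(self) -> float:
        """VPD slope per one-sd increase of VPD (raw beta2)."""
        return float(self.beta[1])

    @property
    def reported_slopes(self) -> dict:
        return {
            "swc": self.swc_slope_drying,
            "vpd": self.vpd_slope,
            "swc_x_vpd": float(self.beta[2]),
            "ta": float(self.beta[3]),
            "rg": float(self.beta[4]),
        }


def fit_standardized_regression(days: pd.DataFrame, response: str = "gpp_nt",
                                site_id: str = "") -> LinearFit:
    """Fit the five-term standardized regression on an already z-scored table.

    The interaction regressor is the product of the standardized SWC and VPD
    series and is not itself re-standardized.
    """
    needed = ["swc", "vpd", "ta", "rg", response]
    for c in needed:
        if c not in days.columns:
            raise ContractError(f"daily table lacks {c!r}")
    d = days[needed].dropna()
    n = len(d)
    if n <= 7:
        raise ContractError(f"need n > 7 days for the fit, got {n}")
    X = pd.DataFrame(
        {
            "swc": d["swc"],
            "vpd": d["vpd"],
            "swc_x_vpd": d["swc"] * d["vpd"],
            "ta": d["ta"],
            "rg": d["rg"],
        }
    )
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("rank-deficient design (collinear predictors)")
    res = sm.OLS(d[response].to_numpy(), design).fit()
    return LinearFit(
        beta=res.params[1:].copy(), intercept=float(res.params[0]),
        se=res.bse[1:].copy(), pvalues=res.pvalues[1:].copy(),
        resid_sd=float(np.sqrt(res.mse_resid)) if n > design.shape[1] else 0.0,
        n=n, site_id=site_id,
    )


def slope_distribution(fits: list[LinearFit]) -> pd.DataFrame:
    """Cross-site mean, SE and 95% CI of the reported slopes, per variable."""
    if len(fits) < 3:
        raise InsufficientReplicationError(
            f"need >=3 sites for a cross-site slope distribution, got {len(fits)}"
        )
    slopes = pd.DataFrame([f.reported_slopes for f in fits],
                          index=[f.site_id or i for i, f in enumerate(fits)])
    mean = slopes.mean()
    se = slopes.std(ddof=1) / np.sqrt(len(fits))
    return pd.DataFrame(
        {
            "mean": mean,
            "se": se,
            "ci_lo": mean - 1.96 * se,
            "ci_hi": mean + 1.96 * se,
            "n_sites": len(fits),
        }
    )


def with_without_year(daily: pd.DataFrame, year: int, response: str = "gpp_nt",
                      site_id: str = "") -> tuple[LinearFit, LinearFit]:
    """Paired fits on all years vs all-but-one extreme year.

    Standardization is recomputed within each subset, matching the convention
    that z-scores are taken over the analyzed period.
    """
    variables = ["swc", "vpd", "ta", "rg", response]

    def _fit(sub: pd.DataFrame) -> LinearFit:
        sub = sub.dropna(subset=variables)
        if len(sub) <= 7:
            raise ContractError(f"subset too small for fit (n={len(sub)})")
        z, _ = zscore(sub, variables)
        return fit_standardized_regression(z, response=response, site_id=site_id)

    fit_all = _fit(daily)
    fit_excl = _fit(daily[daily.index.year != year])
    return fit_all, fit_excl


def summer_subset(daily: pd.DataFrame) -> pd.DataFrame:
    """June-July-August days (the extreme-summer analysis window)."""
    return daily[daily.index.month.isin((6, 7, 8))]
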