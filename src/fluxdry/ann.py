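"""Feed-forward network perturbation sensitivities on percentile-bin grids.

Per site and response variable, a single-hidden-layer network (rectified
hidden units, linear output) maps z-scored daily drivers (Ta, VPD, SWC, Rg)
to the z-scored response. The per-day sensitivity to a driver is the change
in prediction when that driver alone is perturbed by one standard deviation
(= 1 in z-units): SWC is perturbed by -1 sd (drying orientation, so a
negative value means drying reduces the response) and VPD by +1 sd. Per-day
values are medianed per 10x10 SWC x VPD percentile cell, medianed over five
training repeats, then medianed across sites; cross-site cells carry a
standard error and a one-sample t-test against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .errors import ContractError, UsageError

PREDICTORS = ["ta", "vpd", "swc", "rg"]
#: perturbation direction per predictor (z-units); SWC is drying-oriented
DEFAULT_DIRECTIONS = {"ta": 1.0, "vpd": 1.0, "swc": -1.0, "rg": 1.0}

_SEED_MOD = 2**31


@dataclass
class AnnSpec:
    """Training protocol for the sensitivity networks."""

    hidden_nodes: int = 10           # search grid 4..20 step 2 available
    split: tuple = (0.6, 0.2, 0.2)   # train / validation / test
    repeats: int = 5
    max_epochs: int = 1000
    performance_threshold: float = 0.5  # min held-out r; below -> site excluded
    n_restarts: int = 4              # random restarts ranked by validation MSE
    min_days: int = 100
    activation: str = "relu"         # hidden-unit nonlinearity ("relu"|"logistic"|"tanh")

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ContractError("split fractions must sum to 1")
        if self.repeats < 1:
            raise ContractError("repeats must be >= 1")


@dataclass
class AnnFit:
    """A trained predictor with its held-out diagnostics."""

    model: object
    r_test: float
    rmse_test: float
    r_val: float
    seed: int
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def passes(self, threshold: float) -> bool:
        return np.isfinite(self.r_test) and self.r_test >= threshold


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def train_ann(X: pd.DataFrame, y: pd.Series, spec: AnnSpec, seed: int) -> AnnFit:
    """Train one network on standardized predictors.

    The 60/20/20 split is drawn from ``seed``; ``n_restarts`` networks with
    seed-derived initializations are fitted on the training portion by
    full-batch quasi-Newton minimization of the squared error (bounded by
    ``max_epochs`` iterations) and the restart with the lowest validation
    MSE is kept. Test-portion r and RMSE are the exclusion diagnostics.
    """
    Xa = X[PREDICTORS].to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(Xa).all(axis=1) & np.isfinite(ya)
    Xa, ya = Xa[ok], ya[ok]
    n = len(ya)
    if n < spec.min_days:
        raise ContractError(f"train_ann: need >= {spec.min_days} days, got {n}")

    rng = np.random.default_rng(seed % _SEED_MOD)
    perm = rng.permutation(n)
    n_tr = int(round(spec.split[0] * n))
    n_val = int(round(spec.split[1] * n))
    idx_tr = perm[:n_tr]
    idx_val = perm[n_tr:n_tr + n_val]
    idx_te = perm[n_tr + n_val:]

    best = None
    best_val_mse = np.inf
    best_conv = True
    for j in range(spec.n_restarts):
        sub_seed = (seed + 7919 * (j + 1)) % _SEED_MOD
        net = MLPRegressor(
            hidden_layer_sizes=(spec.hidden_nodes,), activation=spec.activation,
            solver="lbfgs", max_iter=spec.max_epochs, random_state=sub_seed,
            alpha=1e-5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(Xa[idx_tr], ya[idx_tr])
        converged = net.n_iter_ < spec.max_epochs
        val_mse = float(np.mean((net.predict(Xa[idx_val]) - ya[idx_val]) ** 2))
        if val_mse < best_val_mse:
            best, best_val_mse, best_conv = net, val_mse, converged

    pred_te = best.predict(Xa[idx_te])
    pred_val = best.predict(Xa[idx_val])
    return AnnFit(
        model=best,
        r_test=_pearson(pred_te, ya[idx_te]),
        rmse_test=float(np.sqrt(np.mean((pred_te - ya[idx_te]) ** 2))),
        r_val=_pearson(pred_val, ya[idx_val]),
        seed=seed, converged=best_conv,
    )


def perturbation_sensitivity(fit, X: pd.DataFrame, variable: str,
                             direction: Optional[float] = None) -> pd.Series:
    """Per-day perturbation sensitivity of the fitted predictor.

    All predictors are held at their observed values; ``variable`` alone is
    shifted by ``direction`` standard deviations (default: -1 for SWC,
    +1 otherwise). With unit-sd inputs the per-day value is simply
    ``f(x_perturbed) - f(x)``.
    """
    if variable not in PREDICTORS:
        raise UsageError(f"unknown predictor {variable!r}; choose from {PREDICTORS}")
    if direction is None:
        direction = DEFAULT_DIRECTIONS[variable]
    Xa = X[PREDICTORS].to_numpy(dtype=float)
    Xp = Xa.copy()
    Xp[:, PREDICTORS.index(variable)] += direction
    base = fit.predict(Xa)
    pert = fit.predict(Xp)
    return pd.Series(pert - base, index=X.index)


@dataclass
class SensitivityGrid:
    """A 10x10 percentile-bin grid of median sensitivities."""

    sens: np.ndarray                     # (10, 10), NaN where empty
    n_days: np.ndarray                   # (10, 10) int
    variable: str = ""
    response: str = ""
    se: Optional[np.ndarray] = None      # cross-site only
    pval: Optional[np.ndarray] = None
    n_sites: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(10):
            for j in range(10):
                rows.append({
                    "i_swc": i + 1, "j_vpd": j + 1,
                    "variable": self.variable, "response": self.response,
                    "median": self.sens[i, j],
                    "n_days": int(self.n_days[i, j]),
                    "se": np.nan if self.se is None else self.se[i, j],
                    "p": np.nan if self.pval is None else self.pval[i, j],
                    "n_sites": 1 if self.n_sites is None else int(self.n_sites[i, j]),
                })
        return pd.DataFrame(rows)


def _cell_median_grid(values: pd.Series, labels: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sens = np.full((10, 10), np.nan)
    n = np.zeros((10, 10), dtype=int)
    joined = pd.DataFrame({"v": values}).join(labels)
    for (i, j), grp in joined.groupby(["i_swc", "j_vpd"]):
        vals = grp["v"].dropna()
        if len(vals):
            sens[i - 1, j - 1] = vals.median()
            n[i - 1, j - 1] = len(vals)
    return sens, n


def bin_aggregate(per_repeat: list[pd.Series], labels: pd.DataFrame,
                  variable: str = "", response: str = "") -> SensitivityGrid:
    """Median per cell within each repeat, then median of medians across repeats."""
    if not per_repeat:
        raise ContractError("bin_aggregate: need >= 1 repeat")
    grids, counts = [], None
    for s in per_repeat:
        g, n = _cell_median_grid(s, labels)
        grids.append(g)
        counts = n if counts is None else np.maximum(counts, n)
    stacked = np.stack(grids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stacked, axis=0)
    return SensitivityGrid(sens=med, n_days=counts, variable=variable, response=response)


def cross_site_grid(site_grids: list[SensitivityGrid]) -> SensitivityGrid:
    """Cross-site median grid with SE (n>=2) and one-sample t-test (n>=3).

    Cells where every contributing site reports an identical nonzero value
    have zero variance; they are treated as significant (p = 0).
    """
    if not site_grids:
        raise ContractError("cross_site_grid: no site grids")
    stacked = np.stack([g.sens for g in site_grids])
    ndays = np.stack([g.n_days for g in site_grids]).sum(axis=0)
    med = np.full((10, 10), np.nan)
    se = np.full((10, 10), np.nan)
    pval = np.full((10, 10), np.nan)
    nsites = np.zeros((10, 10), dtype=int)
    for i in range(10):
        for j in range(10):
            vals = stacked[:, i, j]
            vals = vals[np.isfinite(vals)]
            k = len(vals)
            nsites[i, j] = k
            if k == 0:
                continue
            med[i, j] = np.median(vals)
            if k >= 2:
                se[i, j] = np.std(vals) / np.sqrt(k)
            if k >= 3:
                if np.std(vals, ddof=1) == 0:
                    pval[i, j] = 0.0 if vals[0] != 0 else 1.0
                else:
                    pval[i, j] = float(stats.ttest_1samp(vals, 0.0).pvalue)
    g0 = site_grids[0]
    return SensitivityGrid(sens=med, n_days=ndays, variable=g0.variable,
                           response=g0.response, se=se, pval=pval, n_sites=nsites)


@dataclass
class SiteSensitivityResult:
    """Per-site grids for each perturbed variable plus training diagnostics."""

    site_id: str
    grids: dict = field(default_factory=dict)   # variable -> SensitivityGrid
    r_tests: list = field(default_factory=list)
    excluded: bool = False


def site_sensitivities(X: pd.DataFrame, y: pd.Series, labels: pd.DataFrame,
                       spec: AnnSpec, base_seed: int, site_index: int,
                       variables=("swc", "vpd"), response: str = "",
                       site_id: str = "",
                       swc_direction: Optional[float] = None) -> SiteSensitivityResult:
    """Run the full per-site protocol: repeats, perturbations, bin medians.

    Repeat ``j`` uses seed ``base_seed + 1000*site_index + j``; the site is
    excluded when the median held-out r over repeats falls below the
    performance threshold.
    """
    per_var: dict[str, list[pd.Series]] = {v: [] for v in variables}
    r_tests = []
    for j in range(spec.repeats):
        seed = (base_seed + 1000 * site_index + j) % _SEED_MOD
        fit = train_ann(X, y, spec, seed)
        r_tests.append(fit.r_test)
        for v in variables:
            direction = swc_direction if (v == "swc" and swc_direction is not None) else None
            per_var[v].append(perturbation_sensitivity(fit, X, v, direction))
    excluded = not (np.nanmedian(r_tests) >= spec.performance_threshold)
    grids = {
        v: bin_aggregate(per_var[v], labels, variable=v, response=response)
        for v in variables
    }
    return SiteSensitivityResult(site_id=site_id, grids=grids,
                                 r_tests=r_tests, excluded=excluded)


def sensitivity_vs_truth(grid: SensitivityGrid, truth: SensitivityGrid,
                         min_days: int = 30) -> dict:
    """Per-cell (estimated - true) map and its MAE over well-populated cells."""
    if truth is None:
        raise ContractError("sensitivity_vs_truth: truth grid absent")
    if grid.sens.shape != truth.sens.shape:
        raise ContractError("grid shapes differ")
    diff = grid.sens - truth.sens
    ok = (grid.n_days >= min_days) & np.isfinite(diff)
    mae = float(np.abs(diff[ok]).mean()) if ok.any() else np.nan
    return {"diff": diff, "mae": mae, "n_cells": int(ok.sum())}
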