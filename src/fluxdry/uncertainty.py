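"""Method-choice and sampling uncertainty of sensitivity grids.

Two analysis variants (e.g. night-time vs daytime partitioned GPP, or the
NEE quartile bounds, or LE vs energy-balance-corrected LE) produce two
grids; their cellwise difference is the method uncertainty and its magnitude
relative to the cell mean is the relative uncertainty in percent. Sampling
uncertainty is the cross-site standard error per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import SensitivityGrid
from .errors import ContractError

NEAR_ZERO = 1e-6


@dataclass
class GridDifference:
    """Cellwise variant difference with its relative form."""

    diff: np.ndarray               # a - b, NaN where either missing
    relative_pct: np.ndarray       # 100*|a-b| / |(a+b)/2|
    undefined_high: np.ndarray     # bool: |mean| below threshold (blow-up cells)
    label_a: str = ""
    label_b: str = ""


def grid_difference(grid_a: SensitivityGrid, grid_b: SensitivityGrid) -> np.ndarray:
    """Cellwise a - b; missing wherever either input cell is missing."""
    if grid_a.sens.shape != grid_b.sens.shape:
        raise ContractError("grid shapes differ")
    return grid_a.sens - grid_b.sens


def relative_uncertainty(grid_a: SensitivityGrid, grid_b: SensitivityGrid,
                         near_zero: float = NEAR_ZERO) -> tuple[np.ndarray, np.ndarray]:
    """Percent grid 100*|a-b|/|(a+b)/2| plus an undefined-high flag.

    Cells whose mean magnitude is below ``near_zero`` blow up numerically
    (they are the statistically insignificant cells); they are returned NaN
    with the flag set rather than as infinities.
    """
    diff = grid_difference(grid_a, grid_b)
    mean = (grid_a.sens + grid_b.sens) / 2.0
    undefined = np.isfinite(mean) & (np.abs(mean) < near_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * np.abs(diff) / np.abs(mean)
    rel = np.where(undefined, np.nan, rel)
    return rel, undefined


def compare_variants(grid_a: SensitivityGrid, grid_b: SensitivityGrid,
                     label_a: str = "a", label_b: str = "b") -> GridDifference:
    rel, undefined = relative_uncertainty(grid_a, grid_b)
    return GridDifference(diff=grid_difference(grid_a, grid_b), relative_pct=rel,
                          undefined_high=undefined, label_a=label_a, label_b=label_b)


def cross_site_se(site_grids: list[SensitivityGrid]) -> np.ndarray:
    """Per-cell sd across sites / sqrt(n_sites); NaN below two sites.

    The spread is the population standard deviation of the site values
    (the dispersion of the sites actually observed, not an n-1 estimate).
    """
    if not site_grids:
        raise ContractError("cross_site_se: no grids")
    stacked = np.stack([g.sens for g in site_grids])
    se = np.full(stacked.shape[1:], np.nan)
    it = np.ndindex(*stacked.shape[1:])
    for idx in it:
        vals = stacked[(slice(None),) + idx]
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2:
            se[idx] = np.std(vals) / np.sqrt(len(vals))
    return se


def relative_cross_site_se(site_grids: list[SensitivityGrid],
                           median_grid: SensitivityGrid,
                           near_zero: float = NEAR_ZERO) -> np.ndarray:
    """SE divided by the magnitude of the cross-site median sensitivity."""
    se = cross_site_se(site_grids)
    med = np.abs(median_grid.sens)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(med >= near_zero, se / med, np.nan)
    return rel
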