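"""End-to-end orchestration: simulate -> prep -> derive -> sensitivities ->
decomposition -> uncertainty, as one reproducible, manifest-logged run.

Every stage is deterministic given the run seed; the manifest records the
config hash, per-site eligibility (at least 300 growing-season days), ANN
exclusions (held-out r < 0.5) and every output file, so each table is
regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import synthetic
from .ann import (AnnSpec, SensitivityGrid, SiteSensitivityResult,
                  cross_site_grid, bin_aggregate, site_sensitivities,
                  sensitivity_vs_truth)
from .core import SiteSeries
from .decomposition import decomposition_table, site_decomposition
from .derive import derive_daily
from .errors import ConfigError, ContractError
from .ingest import (PFT_BLACKLIST, aggregate_daytime_daily, assign_bins,
                     filter_growing_season, read_flux_csv, read_site_metadata,
                     zscore)
from .linear import (fit_standardized_regression, slope_distribution,
                     summer_subset)
from .uncertainty import compare_variants
from .synthetic import TruthParams

log = logging.getLogger("fluxdry")

_CONFIG_FIELDS = {
    "input_dir", "n_sites", "n_days", "seed", "swc_layer", "season_mode",
    "le_variant", "responses", "hidden_nodes", "repeats", "n_restarts",
    "min_days", "min_cell", "exclude_pfts", "derive", "write_inputs",
    "truth", "model_comparison", "model_truth", "n_model_sites",
}


@dataclass
class RunConfig:
    """Validated configuration of one observational run."""

    input_dir: Optional[str] = None    # read CSVs from here; None -> simulate
    n_sites: int = 20
    n_days: int = 1095
    seed: int = 0
    swc_layer: int = 1
    season_mode: str = "threshold"
    le_variant: str = "le"
    responses: tuple = ("gpp_nt", "gpp_dt")
    hidden_nodes: int = 10
    repeats: int = 5
    n_restarts: int = 4
    min_days: int = 100
    min_cell: int = 3
    exclude_pfts: tuple = PFT_BLACKLIST
    derive: bool = False
    write_inputs: bool = False
    truth: dict = field(default_factory=dict)       # TruthParams overrides
    model_comparison: bool = False
    model_truth: dict = field(default_factory=dict)  # overrides for the model generator
    n_model_sites: int = 3

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if cfg.swc_layer not in (1, 2, 3, 4):
            raise ConfigError("swc_layer must be 1..4")
        if cfg.season_mode not in ("threshold", "peak3mo", "deseason"):
            raise ConfigError(f"unknown season_mode {cfg.season_mode!r}")
        if cfg.le_variant not in ("le", "le_corr"):
            raise ConfigError(f"unknown le_variant {cfg.le_variant!r}")
        # reject unknown truth overrides before any compute
        cfg.truth_params()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def truth_params(self) -> TruthParams:
        base = TruthParams(seed=self.seed, n_sites=self.n_sites, n_days=self.n_days)
        return base.with_overrides(**dict(self.truth))

    def ann_spec(self) -> AnnSpec:
        return AnnSpec(hidden_nodes=self.hidden_nodes, repeats=self.repeats,
                       n_restarts=self.n_restarts, min_days=self.min_days)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PreppedSite:
    """One site after aggregation, selection, standardization and binning."""

    site_id: str
    site_index: int
    pft: str
    days: pd.DataFrame        # raw selected days
    days_z: pd.DataFrame      # z-scored (plus rg_raw column)
    zparams: object
    labels: pd.DataFrame
    eligible: bool
    n_selected: int
    series: Optional[SiteSeries] = None


def load_sites(config: RunConfig) -> list[SiteSeries]:
    """Simulate sites or read them from ``input_dir`` (with sites.yaml metadata)."""
    if config.input_dir is None:
        params = config.truth_params()
        return [synthetic.simulate_site(params, i) for i in range(config.n_sites)]
    root = Path(config.input_dir)
    meta = read_site_metadata(root / "sites.yaml")
    sites = []
    for i, (site_id, m) in enumerate(sorted(meta.items())):
        s = read_flux_csv(root / f"{site_id}.csv", site_id=site_id,
                          pft=m.get("pft", "unknown"), zm=m.get("zm", np.nan),
                          swc_layers=(config.swc_layer,))
        s.site_index = i
        sites.append(s)
    return sites


def prepare_site(series: SiteSeries, config: RunConfig,
                 extra_responses: tuple = ()) -> Optional[PreppedSite]:
    """Aggregate, select growing-season days, standardize and bin one site.

    Returns None when the site is PFT-blacklisted or has too few selected
    days for the network stage.
    """
    if series.pft in config.exclude_pfts:
        log.info("site %s: PFT %s excluded", series.site_id, series.pft)
        return None
    daily = aggregate_daytime_daily(series, swc_layer=config.swc_layer)
    frame = daily.data
    if config.derive or extra_responses:
        derived = derive_daily(series, le_variant=config.le_variant)
        frame = frame.join(derived.drop(columns=["ta_mid", "gpp_day"], errors="ignore"),
                           how="left")
    sel = filter_growing_season(frame, mode=config.season_mode)
    base_vars = ["swc", "vpd", "ta", "rg"]
    responses = [r for r in (*config.responses, *extra_responses) if r in frame.columns]
    need = base_vars + responses
    days = sel.days.dropna(subset=base_vars + [responses[0]] if responses else base_vars)
    if len(days) < max(config.min_days, 10):
        log.info("site %s: only %d selected days, skipped", series.site_id, len(days))
        return None
    days_z, zparams = zscore(days, [v for v in need if days[v].notna().sum() >= 2])
    days_z = days_z.copy()
    days_z["rg_raw"] = days["rg"]
    grid, labels = assign_bins(days)
    return PreppedSite(site_id=series.site_id, site_index=series.site_index,
                       pft=series.pft, days=days, days_z=days_z, zparams=zparams,
                       labels=labels, eligible=sel.eligible,
                       n_selected=sel.n_selected, series=series)


def truth_grid_for_site(prep: PreppedSite, params: TruthParams,
                        response: str = "gpp_nt") -> dict[str, SensitivityGrid]:
    """Analytic oracle grids matching the site's bins and standardization."""
    zp = prep.zparams
    sens = synthetic.true_perturbation_sensitivities(
        params, prep.days, sd_swc=float(zp.sds["swc"]), sd_vpd=float(zp.sds["vpd"]),
        sd_gpp=float(zp.sds[response]),
    )
    return {
        "swc": bin_aggregate([sens["s_swc"]], prep.labels, "swc", response + "_truth"),
        "vpd": bin_aggregate([sens["s_vpd"]], prep.labels, "vpd", response + "_truth"),
    }


@dataclass
class RunResult:
    """In-memory results of one observational run."""

    config: RunConfig
    prepped: list
    grids: dict                  # (response, variable) -> cross-site SensitivityGrid
    site_results: dict           # response -> list[SiteSensitivityResult]
    slopes: Optional[pd.DataFrame]
    slopes_summary: Optional[pd.DataFrame]
    decomposition: pd.DataFrame
    uncertainty: dict
    truth_error: dict            # response -> {"diff","mae","n_cells"}
    truth_grids: dict            # variable -> cross-site truth SensitivityGrid
    manifest: dict


def run_observational(config: RunConfig, out_dir=None) -> RunResult:
    """Execute the full observational pipeline; optionally write all tables."""
    t0 = time.time()
    sites = load_sites(config)
    params = config.truth_params() if config.input_dir is None else None

    out = Path(out_dir) if out_dir is not None else None
    written: list[str] = []
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "grids").mkdir(exist_ok=True)

    if config.write_inputs and out is not None:
        csv_dir = out / "site_csv"
        csv_dir.mkdir(exist_ok=True)
        for s in sites:
            written.append(str(synthetic.write_fluxnet_csv(s, csv_dir / f"{s.site_id}.csv")))
        written.append(str(synthetic.write_site_metadata(sites, csv_dir / "sites.yaml")))

    prepped: list[PreppedSite] = []
    for s in sites:
        try:
            p = prepare_site(s, config)
        except ContractError as exc:
            raise ContractError(f"prep stage failed at site {s.site_id}: {exc}") from exc
        if p is not None:
            prepped.append(p)
    log.info("prepared %d/%d sites (%.1fs)", len(prepped), len(sites), time.time() - t0)

    # --- linear stage (summer subset, per site) ---
    fits = []
    for p in prepped:
        jja = summer_subset(p.days)
        variables = ["swc", "vpd", "ta", "rg", "gpp_nt"]
        jja = jja.dropna(subset=variables)
        if len(jja) > 7:
            z, _ = zscore(jja, variables)
            try:
                fits.append(fit_standardized_regression(z, "gpp_nt", site_id=p.site_id))
            except ContractError:
                pass
    slopes = pd.DataFrame([dict(site=f.site_id, n=f.n, **f.reported_slopes) for f in fits]) \
        if fits else None
    slopes_summary = slope_distribution(fits) if len(fits) >= 3 else None

    # --- ANN sensitivity stage ---
    spec = config.ann_spec()
    site_results: dict[str, list[SiteSensitivityResult]] = {}
    grids: dict[tuple, SensitivityGrid] = {}
    exclusions: dict[str, list[str]] = {}
    for response in config.responses:
        results = []
        for p in prepped:
            if response not in p.days_z.columns:
                continue
            res = site_sensitivities(
                p.days_z, p.days_z[response], p.labels, spec,
                base_seed=config.seed, site_index=p.site_index,
                response=response, site_id=p.site_id,
            )
            results.append(res)
        site_results[response] = results
        kept = [r for r in results if not r.excluded]
        exclusions[response] = [r.site_id for r in results if r.excluded]
        for variable in ("swc", "vpd"):
            if kept:
                grids[(response, variable)] = cross_site_grid(
                    [r.grids[variable] for r in kept]
                )
    log.info("ANN stage done (%.1fs)", time.time() - t0)

    # --- truth oracle and error maps (synthetic provenance only) ---
    truth_error: dict = {}
    truth_grids: dict = {}
    if params is not None and "gpp_nt" in config.responses:
        tgrids = {"swc": [], "vpd": []}
        for p in prepped:
            tg = truth_grid_for_site(p, params, "gpp_nt")
            for v in ("swc", "vpd"):
                tgrids[v].append(tg[v])
        for v in ("swc", "vpd"):
            truth_grids[v] = cross_site_grid(tgrids[v])
            if ("gpp_nt", v) in grids:
                truth_error[v] = sensitivity_vs_truth(grids[("gpp_nt", v)], truth_grids[v])

    # --- decomposition ---
    per_site_decomp = {
        p.site_id: site_decomposition(p.days_z, p.days, p.labels,
                                      min_cell=config.min_cell)
        for p in prepped
    }
    decomp = decomposition_table(per_site_decomp)

    # --- uncertainty (variant comparisons) ---
    unc = {}
    if ("gpp_nt", "swc") in grids and ("gpp_dt", "swc") in grids:
        for v in ("swc", "vpd"):
            unc[f"nt_vs_dt_{v}"] = compare_variants(
                grids[("gpp_nt", v)], grids[("gpp_dt", v)], "gpp_nt", "gpp_dt"
            )

    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "sites": [
            {
                "site_id": p.site_id, "pft": p.pft,
                "n_selected": int(p.n_selected), "eligible": bool(p.eligible),
            }
            for p in prepped
        ],
        "n_sites_input": len(sites),
        "n_sites_prepped": len(prepped),
        "n_eligible": int(sum(p.eligible for p in prepped)),
        "ann_exclusions": exclusions,
        "outputs": [],
    }

    result = RunResult(config=config, prepped=prepped, grids=grids,
                       site_results=site_results, slopes=slopes,
                       slopes_summary=slopes_summary, decomposition=decomp,
                       uncertainty=unc, truth_error=truth_error,
                       truth_grids=truth_grids, manifest=manifest)
    if out is not None:
        written += _write_outputs(result, out)
        manifest["outputs"] = sorted(str(Path(w).relative_to(out)) for w in written)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    log.info("run complete (%.1fs)", time.time() - t0)
    return result


def _write_outputs(result: RunResult, out: Path) -> list[str]:
    written = []

    def save(df: pd.DataFrame, rel: str) -> None:
        path = out / rel
        df.to_csv(path, index=False)
        written.append(str(path))

    for (response, variable), grid in sorted(result.grids.items()):
        save(grid.to_frame(), f"grids/{response}_{variable}.csv")
    for variable, grid in sorted(result.truth_grids.items()):
        save(grid.to_frame(), f"grids/truth_gpp_nt_{variable}.csv")
    if result.slopes is not None:
        save(result.slopes, "slopes.csv")
    if result.slopes_summary is not None:
        save(result.slopes_summary.reset_index(names="variable"), "slopes_summary.csv")
    if len(result.decomposition):
        save(result.decomposition, "decomposition.csv")
    for name, gd in sorted(result.uncertainty.items()):
        rows = []
        for i in range(10):
            for j in range(10):
                rows.append({"i_swc": i + 1, "j_vpd": j + 1,
                             "diff": gd.diff[i, j],
                             "relative_pct": gd.relative_pct[i, j],
                             "undefined_high": bool(gd.undefined_high[i, j])})
        save(pd.DataFrame(rows), f"uncertainty_{name}.csv")
    for variable, err in sorted(result.truth_error.items()):
        rows = []
        for i in range(10):
            for j in range(10):
                rows.append({"i_swc": i + 1, "j_vpd": j + 1, "diff": err["diff"][i, j]})
        df = pd.DataFrame(rows)
        df["mae"] = err["mae"]
        save(df, f"truth_error_gpp_nt_{variable}.csv")
    return written


def run_model_comparison(obs_grids: dict, model_series: list[pd.DataFrame],
                         spec: AnnSpec, seed: int,
                         variables=("swc", "vpd")) -> dict:
    """ESM-style comparison: ANN sensitivities of daily model output minus
    the observation-based grids.

    ``model_series`` are daily frames with gpp, tas, rsds, mrsos, vpd
    columns (no biophysics stage: models provide GPP only, at daily step).
    """
    from .errors import SchemaError

    site_grids: dict[str, list] = {v: [] for v in variables}
    warnings_out = []
    for k, df in enumerate(model_series):
        need = ["gpp", "tas", "rsds", "mrsos", "vpd"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise SchemaError(f"model series {k}: missing columns {missing}")
        if len(df) < 730:
            warnings_out.append(f"model series {k}: shorter than 2 years")
        days = pd.DataFrame({
            "gpp_nt": df["gpp"], "ta": df["tas"], "rg": df["rsds"],
            "swc": df["mrsos"], "vpd": df["vpd"],
        }).dropna()
        days = days[(days["ta"] > 15.0) & (days["vpd"] > 0.5) & (days["rg"] > 250.0)]
        if len(days) < spec.min_days:
            warnings_out.append(f"model series {k}: too few selected days, skipped")
            continue
        days_z, _ = zscore(days, ["gpp_nt", "ta", "rg", "swc", "vpd"])
        _, labels = assign_bins(days)
        res = site_sensitivities(days_z, days_z["gpp_nt"], labels, spec,
                                 base_seed=seed, site_index=k,
                                 response="gpp_model", site_id=f"MODEL-{k:02d}")
        for v in variables:
            site_grids[v].append(res.grids[v])

    out = {"warnings": warnings_out, "model_grids": {}, "difference": {}}
    for v in variables:
        if not site_grids[v]:
            continue
        mg = cross_site_grid(site_grids[v])
        out["model_grids"][v] = mg
        if v in obs_grids:
            out["difference"][v] = mg.sens - obs_grids[v].sens
    return out


def demo_config(seed: int = 42) -> RunConfig:
    """Reduced-scale full-study configuration used by ``fluxdry demo``."""
    return RunConfig(
        n_sites=5, n_days=1095, seed=seed, responses=("gpp_nt", "gpp_dt"),
        repeats=3, n_restarts=2, derive=False, write_inputs=False,
        model_comparison=True, model_truth={"vpd_decay": 0.0},
        n_model_sites=3,
    )


def run_demo(out_dir, seed: int = 42) -> RunResult:
    """One-command reduced-scale reproduction of the whole synthetic study."""
    config = demo_config(seed)
    result = run_observational(config, out_dir=out_dir)
    if config.model_comparison and ("gpp_nt", "swc") in result.grids:
        params = config.truth_params().with_overrides(
            **{**dict(config.model_truth)}
        )
        model_series = [
            synthetic.simulate_model_daily(params, 100 + k)
            for k in range(config.n_model_sites)
        ]
        obs = {v: result.grids[("gpp_nt", v)] for v in ("swc", "vpd")}
        comp = run_model_comparison(obs, model_series, config.ann_spec(), seed=config.seed)
        rows = []
        for v, diff in comp["difference"].items():
            for i in range(10):
                for j in range(10):
                    rows.append({"variable": v, "i_swc": i + 1, "j_vpd": j + 1,
                                 "diff": diff[i, j]})
        if rows and out_dir is not None:
            pd.DataFrame(rows).to_csv(Path(out_dir) / "model_minus_obs.csv", index=False)
        result.manifest["model_comparison_warnings"] = comp["warnings"]
    return result
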