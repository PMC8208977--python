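"""End-to-end orchestration: tracks -> HMM -> behaviors -> models -> syndrome.

One :class:`RunConfig` drives the whole analysis.  Every stage writes
delimited-text outputs plus a JSON manifest (seed, resolved config,
exclusion log), and the run is deterministic given the seed.  Stages
communicate only through the declared table contracts, so each can also
be run on its own from the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import hmm, metrics, mixed, simulate, syndrome, tracks

logger = logging.getLogger("elemove")

RESPONSE_TRANSFORMS = {"home_range_km2": "log"}
BEHAVIOR_RESPONSES = (
    "distance_km",
    "home_range_km2",
    "site_fidelity",
    "diurnality",
    "exploratory_prop",
)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the analysis constants.

    Speed threshold 7 km/h, 2-h burst gap, 95% isopleth, 250-m KDE cells,
    the 06:00-18:00 day window and the reference prior/MCMC constants are
    the fixed study conditions; everything is overridable.
    """

    # paths (None -> simulate a population instead of reading tracks)
    tracks_path: str | None = None
    out_dir: str = "elemove_out"
    # cleaning
    v_max_kmh: float = 7.0
    gap_max_hours: float = 2.0
    utc_offset_hours: float = 0.0
    # hmm
    n_restarts: int = 10
    # behavior metrics
    cell: float = 250.0
    isopleth: float = 0.95
    min_coverage: float = 0.5
    h_override_monthly: float | None = None
    h_override_annual: float | None = None
    scales: tuple = ("monthly",)
    # models
    mcmc_iterations: int = 8_500
    mcmc_burnin: int = 500
    mcmc_thin: int = 4
    # simulation (used when tracks_path is None)
    n_individuals: int = 12
    months: int = 6
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        if isinstance(cfg.scales, list):
            cfg.scales = tuple(cfg.scales)
        return cfg

    def preset(self) -> mixed.McmcPreset:
        return mixed.McmcPreset(self.mcmc_iterations, self.mcmc_burnin, self.mcmc_thin)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("ingest")
def stage_ingest(cfg: RunConfig):
    """Read or simulate tracks; returns (trajectories, rasters, truth|None)."""
    if cfg.tracks_path is not None:
        trajs = tracks.read_tracks(
            cfg.tracks_path, utc_offset_hours=cfg.utc_offset_hours
        )
        return trajs, None, None
    sim_cfg = simulate.SimConfig(
        n_individuals=cfg.n_individuals, months=cfg.months, seed=cfg.seed
    )
    rasters = simulate.generate_rasters(
        sim_cfg.raster_spec, seed=cfg.seed + 1, months=sim_cfg.month_labels
    )
    trajs, truth = simulate.simulate_population(sim_cfg, rasters)
    return trajs, rasters, truth


def load_rasters(raster_dir) -> dict:
    """Read a covariate raster set from ASCII grids (the layout written
    by the ``simulate`` subcommand): static ``<name>.asc`` plus monthly
    ``monthly_<var>_<YYYY-MM>.asc`` layers."""
    from .rasters import RasterGrid, annual_ndvi, ndvi_gapfill

    raster_dir = Path(raster_dir)
    out: dict = {"monthly_rainfall": {}, "monthly_ndvi": {}}
    for name in ("hfi", "temp_seasonality", "annual_rainfall"):
        path = raster_dir / f"{name}.asc"
        if path.exists():
            out[name] = RasterGrid.read_ascii(path, label=name)
    for path in sorted(raster_dir.glob("monthly_*_*.asc")):
        kind, month = path.stem.rsplit("_", 1)
        if kind in out:
            out[kind][month] = RasterGrid.read_ascii(path, label=kind, time_index=month)
    if out["monthly_ndvi"]:
        months = sorted(out["monthly_ndvi"])
        filled = ndvi_gapfill([out["monthly_ndvi"][m] for m in months])
        out["monthly_ndvi"] = dict(zip(months, filled))
        out["annual_ndvi"] = annual_ndvi(filled)
    return out


@_stage("clean")
def stage_clean(cfg: RunConfig, trajs):
    cleaned = [
        tracks.segment_bursts(
            tracks.filter_speed(tr, cfg.v_max_kmh), cfg.gap_max_hours
        )
        for tr in trajs
    ]
    report = tracks.regularity_report(cleaned)
    return cleaned, report


@_stage("hmm")
def stage_hmm(cfg: RunConfig, cleaned):
    steps = hmm.pool_step_series([hmm.build_step_series(tr) for tr in cleaned])
    params, report = hmm.fit_hmm(steps, n_restarts=cfg.n_restarts, seed=cfg.seed + 2)
    steps["state"] = hmm.viterbi_decode(params, steps)
    return steps, params, report


@_stage("metrics")
def stage_metrics(cfg: RunConfig, cleaned, steps, rasters, scale: str):
    h_override = (
        cfg.h_override_monthly if scale == "monthly" else cfg.h_override_annual
    )
    return metrics.assemble_behavior_table(
        cleaned,
        steps,
        scale=scale,
        rasters=rasters,
        min_coverage=cfg.min_coverage,
        h_override=h_override,
        cell=cfg.cell,
        isopleth=cfg.isopleth,
    )


def _available_fixed(table: pd.DataFrame) -> tuple:
    """Fixed effects actually estimable from a behavior table: present
    columns only, and sex only when both levels occur."""
    fixed = []
    if "sex" in table.columns and table["sex"].nunique() > 1:
        fixed.append("sex")
    fixed += [
        c for c in mixed.CONTINUOUS_COVARIATES
        if c in table.columns and table[c].notna().any()
    ]
    return tuple(fixed)


@_stage("univariate")
def stage_univariate(cfg: RunConfig, table: pd.DataFrame, scale: str):
    preset = cfg.preset()
    random_terms = (
        ("individual", "region", "month") if scale == "monthly" else ("individual", "region")
    )
    fixed = _available_fixed(table)
    if len(fixed) < 5:
        logger.warning(
            "covariate columns missing from the behavior table; fitting with "
            "fixed effects %s only", fixed,
        )
    results = {}
    for i_resp, resp in enumerate(BEHAVIOR_RESPONSES):
        if table[resp].notna().sum() < 10 or table[resp].std() == 0:
            logger.warning("skipping %s at %s scale: insufficient data", resp, scale)
            continue
        spec = mixed.ModelSpec(
            response=resp,
            transform=RESPONSE_TRANSFORMS.get(resp, "identity"),
            fixed=fixed,
            random=random_terms,
            mcmc=preset,
            seed=cfg.seed + 10 + i_resp,
        )
        draws = mixed.fit_univariate(table, spec)
        results[resp] = {
            "draws": draws,
            "effects": mixed.fixed_effect_summary(draws),
            "repeatability": mixed.repeatability(draws),
            "r2": mixed.r_squared(draws),
        }
        if resp == "site_fidelity":
            results[resp]["caveat"] = (
                "site-fidelity models are prone to low effective sample sizes; "
                "interpret with caution"
            )
    return results


@_stage("syndrome")
def stage_syndrome(cfg: RunConfig, monthly_table: pd.DataFrame):
    fixed = _available_fixed(monthly_table)
    spec = syndrome.MultiSpec(
        transforms={"home_range_km2": "log"},
        fixed=fixed,
        mcmc=cfg.preset(),
        seed=cfg.seed + 20,
    )
    draws = syndrome.fit_multivariate(monthly_table, spec)
    corr = syndrome.among_individual_correlations(draws)
    axes = syndrome.eigen_syndrome(draws)
    return draws, corr, axes


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the output bundle to ``cfg.out_dir``.

    Outputs: regularity report, fitted HMM parameters, decoded step
    series, behavior tables, effect-size and repeatability tables,
    R^2 table, the among-individual matrix summary, syndrome loadings,
    and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "stages": [],
    }

    def done(stage):
        manifest["stages"].append(stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        trajs, rasters, truth = stage_ingest(cfg)
        done("ingest")
        cleaned, regularity = stage_clean(cfg, trajs)
        regularity.to_csv(out / "regularity.csv", index=False)
        done("clean")
        steps, params, hmm_report = stage_hmm(cfg, cleaned)
        with open(out / "hmm_params.json", "w") as fh:
            json.dump({"params": params.to_dict(), "report": hmm_report}, fh, indent=2)
        steps.to_csv(out / "steps_decoded.csv", index=False)
        done("hmm")

        tables = {}
        exclusions = []
        for scale in cfg.scales:
            tab = stage_metrics(cfg, cleaned, steps, rasters, scale)
            tab.to_csv(out / f"behavior_{scale}.csv", index=False)
            exclusions.extend(tab.attrs["exclusions"])
            manifest[f"h_used_{scale}"] = tab.attrs["h_used"]
            tables[scale] = tab
        manifest["exclusions"] = exclusions
        done("metrics")

        uni = {}
        effect_rows, rep_rows, r2_rows = [], [], []
        for scale, tab in tables.items():
            uni[scale] = stage_univariate(cfg, tab, scale)
            for resp, res in uni[scale].items():
                eff = res["effects"].copy()
                eff.insert(0, "response", resp)
                eff.insert(0, "scale", scale)
                effect_rows.append(eff)
                rep_rows.append({"scale": scale, "response": resp, **res["repeatability"]})
                r2 = res["r2"]
                r2_rows.append(
                    {
                        "scale": scale,
                        "response": resp,
                        "marginal": r2["marginal"],
                        "conditional": r2["conditional"],
                    }
                )
        pd.concat(effect_rows, ignore_index=True).to_csv(out / "effects.csv", index=False)
        pd.DataFrame(rep_rows).to_csv(out / "repeatability.csv", index=False)
        pd.DataFrame(r2_rows).to_csv(out / "r_squared.csv", index=False)
        done("univariate")

        results: dict = {
            "trajectories": cleaned,
            "steps": steps,
            "hmm_params": params,
            "tables": tables,
            "univariate": uni,
            "manifest": manifest,
            "truth": truth,
        }
        if "monthly" in tables:
            draws, corr, axes = stage_syndrome(cfg, tables["monthly"])
            syndrome.table2_style(draws).to_csv(out / "among_individual_matrix.csv")
            syndrome.loadings_table(axes).to_csv(out / "syndrome_loadings.csv", index=False)
            results["syndrome"] = {"draws": draws, "correlations": corr, "axes": axes}
            done("syndrome")
        return results
    except RuntimeError:
        with open(out / "manifest.json", "w") as fh:
            manifest["failed"] = True
            json.dump(manifest, fh, indent=2, default=str)
        raise
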