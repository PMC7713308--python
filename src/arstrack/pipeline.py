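"""End-to-end orchestration, summary tables and the ancestry rule.

``run_pipeline`` executes read → segment → state-space fit → metrics /
occupancy → covariate extraction → collinearity screen → additive model
→ multiple-imputation significance, writing every artifact plus a run
manifest.  Every stochastic stage consumes a seed derived
deterministically from the global seed and the stage name, so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from arstrack.argos_io import read_argos, segment_all
from arstrack.habitat import GammSpec, fit_gamm, imputation_significance
from arstrack.movement import (
    McmcPlan,
    ModelSpec,
    export_state_series,
    fit_hssm,
)
from arstrack.occupancy import GSACUS, RegionMask, occupancy, track_metrics
from arstrack.seascape import ExtractionSpec, extract, screen_collinearity
from arstrack.simulate import SeascapeFieldSet

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# ancestry classification


@dataclass(frozen=True)
class AncestryCall:
    """Subspecies ancestry classification for one individual."""

    individual_id: str
    pygmy_fraction: float
    call: str  # pure_pygmy | pure_antarctic | admixed


def classify_ancestry(pygmy_fraction: float, individual_id: str = "") -> AncestryCall:
    """Classify an individual by its estimated pygmy ancestry fraction.

    At least 98% pygmy ancestry → 'pure' pygmy blue whale; no more than
    12% → 'pure' Antarctic blue whale; anything in between → admixed.
    Both boundaries are inclusive.
    """
    f = float(pygmy_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"ancestry fraction must lie in [0, 1], got {f}")
    if f >= 0.98:
        call = "pure_pygmy"
    elif f <= 0.12:
        call = "pure_antarctic"
    else:
        call = "admixed"
    return AncestryCall(individual_id=individual_id, pygmy_fraction=f, call=call)


# ---------------------------------------------------------------------------
# summary tables


def summary_table(metrics: list) -> tuple[pd.DataFrame, dict]:
    """Per-whale metric rows plus aggregate statistics.

    Aggregates (min/max/mean/SD) cover duration, distance, speed and
    region days; the SD is the sample SD (ddof = 1), zero for a single
    whale.
    """
    if not metrics:
        raise ValueError("need at least one whale")
    rows = []
    for m in metrics:
        rows.append(
            {
                "tag_id": m.tag_id,
                "duration_days": m.track_duration_days,
                "n_locations": m.n_state_locations,
                "distance_km": m.distance_km,
                "mean_speed_kmh": m.mean_speed_kmh,
                "region_days": m.days_in_region,
            }
        )
    table = pd.DataFrame(rows)
    agg = {}
    for col in ("duration_days", "distance_km", "mean_speed_kmh", "region_days"):
        v = table[col].dropna().to_numpy(dtype=float)
        if len(v) == 0:
            continue
        agg[col] = {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        }
    return table, agg


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run."""

    observations: str = ""
    rasters: str = ""
    output_dir: str = "arstrack_out"
    gap_hours: float = 48.0
    min_obs: int = 20
    model: ModelSpec = field(default_factory=ModelSpec)
    plan: McmcPlan = field(default_factory=McmcPlan)
    gamm: GammSpec = field(default_factory=GammSpec)
    extraction: ExtractionSpec = field(default_factory=ExtractionSpec)
    region: RegionMask = field(default_factory=lambda: GSACUS)
    n_imputations: int = 100
    run_habitat: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("observations", "rasters", "output_dir", "gap_hours", "min_obs",
                    "n_imputations", "run_habitat", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "plan" in raw:
            cfg.plan = McmcPlan(**raw["plan"])
        if "model" in raw:
            cfg.model = ModelSpec(**raw["model"])
        if "gamm" in raw:
            cfg.gamm = GammSpec(**raw["gamm"])
        if "extraction" in raw:
            ex = dict(raw["extraction"])
            if ex.get("wind_point") is not None:
                ex["wind_point"] = tuple(ex["wind_point"])
            cfg.extraction = ExtractionSpec(**ex)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write artifacts under ``output_dir``.

    Stage failures raise with the stage name; partial outputs written up
    to that point are preserved.  Returns a manifest dict (also written
    as ``manifest.json``) including convergence flags.
    """
    from arstrack import __version__ as pkg_version

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "arstrack_version": pkg_version,
        "seed": config.seed,
        "stages": [],
        "parameters": {
            "gap_hours": config.gap_hours,
            "min_obs": config.min_obs,
            "dt": config.model.dt,
            "plan": {
                "n_chains": config.plan.n_chains,
                "burn_in": config.plan.burn_in,
                "post_burn_in": config.plan.post_burn_in,
                "thin": config.plan.thin,
            },
            "n_imputations": config.n_imputations,
        },
    }

    def _stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    if config.run_habitat and not config.rasters:
        raise FileNotFoundError(
            "stage seascape_extract: habitat stage enabled but no raster path "
            "configured (set rasters: or run_habitat: false)"
        )
    if config.run_habitat and not Path(config.rasters).exists():
        raise FileNotFoundError(
            f"stage seascape_extract: raster file not found: {config.rasters}"
        )

    _stage("read_argos")
    obs, report = read_argos(config.observations, return_report=True)
    manifest["n_observations"] = int(report.n_valid)
    manifest["n_rejected_rows"] = int(report.n_rejected)

    _stage("segment")
    segments = segment_all(obs, config.gap_hours, config.min_obs)
    if not segments:
        raise RuntimeError("stage segment: no segments survive filtering")
    manifest["n_segments"] = len(segments)

    _stage("fit_hssm")
    plan = config.plan
    plan.seed = stage_seed(config.seed, "fit_hssm")
    series, draws, conv = fit_hssm(segments, config.model, plan)
    export_state_series(series, out / "state_series.csv")
    conv.table.to_csv(out / "convergence.csv", index=False)
    manifest["converged"] = bool(conv.converged)
    manifest["convergence_notes"] = conv.notes

    _stage("metrics_occupancy")
    by_whale: dict[str, list] = {}
    for s in series:
        by_whale.setdefault(s.tag_id, []).append(s)
    metrics = []
    for tag, ss in by_whale.items():
        m = track_metrics(ss, dt_hours=config.model.dt, region=config.region)
        metrics.append(m)
    table, agg = summary_table(metrics)
    table.to_csv(out / "track_metrics.csv", index=False)
    grid = occupancy(by_whale, dt_hours=config.model.dt)
    grid.to_csv(out / "occupancy.csv")
    manifest["aggregates"] = agg
    manifest["occupancy_total_weighted_days"] = grid.total_weighted_days

    if config.run_habitat:
        _stage("seascape_extract")
        fields = SeascapeFieldSet.from_netcdf(config.rasters)
        loc = pd.concat([s.data for s in series], ignore_index=True)
        inside = config.region(loc["lon"].to_numpy(), loc["lat"].to_numpy())
        loc = loc[inside]
        matrix, meta = extract(
            loc, fields, config.extraction, variables=config.gamm.covariates
        )
        matrix.to_csv(out / "covariates.csv", index=False)
        with open(out / "covariates_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)

        _stage("collinearity_screen")
        screen = screen_collinearity(
            matrix, columns=[c for c in config.gamm.covariates if c in matrix.columns]
        )
        manifest["collinearity_dropped"] = screen.dropped
        kept = [c for c in config.gamm.covariates if c in screen.kept]
        gamm_spec = GammSpec(
            covariates=kept,
            k=config.gamm.k,
            degree=config.gamm.degree,
            alpha=config.gamm.alpha,
            random_effect=config.gamm.random_effect,
        )

        _stage("fit_gamm")
        fit = fit_gamm(matrix, gamm_spec)
        fit.smooths.to_csv(out / "gamm_smooths.csv", index=False)
        for cov, curve in fit.curves.items():
            curve.to_csv(out / f"smooth_{cov}.csv", index=False)
        manifest["gamm"] = {
            "intercept": fit.intercept,
            "intercept_se": fit.intercept_se,
            "r2_adjusted": fit.r2_adjusted,
            "n_obs": fit.n_obs,
        }

        _stage("imputation_significance")
        summary = imputation_significance(
            draws,
            fields,
            gamm_spec,
            config.extraction,
            n_iter=config.n_imputations,
            region=config.region,
            seed=stage_seed(config.seed, "imputation"),
        )
        manifest["imputation_counts"] = summary.counts
        manifest["imputation_failures"] = summary.n_failures
        summary.chi_square.to_csv(out / "imputation_chisq.csv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
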