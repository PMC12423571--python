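"""End-to-end orchestration of the three-model analysis.

From a landscape bundle (simulated or loaded from files) the pipeline
builds the assemblage grid, attaches footprint and environmental principal
components, computes replicate-specific trait metrics for every imputation
replicate, fits and prunes the a priori path model on the full table (the
downsizing hypothesis) and on the mega / non-mega subsets (the legacy
hypothesis), and runs permutation-null and spatial robustness checks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assemblage import (
    FilterRules,
    Grid,
    MEGA_SEED_THRESHOLD_MM,
    assemblage_metrics,
    build_grid,
    classify_mega_seeded,
    filter_assemblages,
    rasterize_points,
    rasterize_ranges,
    split_by_mega,
)
from .environment import pca, summarize_raster
from .model import PathModel, default_downsizing_model
from .pooling import PruneTrace, prune_stepwise
from .sem import SemData, SemFit, preprocess_variables
from .spatial import build_weights, fit_sar_error, morans_i, permutation_null
from .synthetic import LandscapeBundle, SimConfig, simulate_landscape

logger = logging.getLogger("seedpath")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compute_r_squared"]

MODEL_VARIABLES = ["seed", "mass_extant", "mass_extinct", "footprint", "pc1", "pc2"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    simulate: SimConfig | None = None
    bundle: LandscapeBundle | None = None
    cell_size: float = 30_000.0
    filters: FilterRules = field(default_factory=FilterRules)
    mega_threshold: float = MEGA_SEED_THRESHOLD_MM
    alpha: float = 0.05
    robust: bool = True
    n_perm: int = 1000
    run_permutation: bool = True
    run_spatial: bool = True
    min_rows: int = 25  # subsets smaller than this are skipped with a notice
    master_seed: int = 0
    model: PathModel | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.bundle is None):
            raise ValueError("provide exactly one of simulate config or bundle")
        if self.mega_threshold <= 0 or self.cell_size <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RunReport:
    """Per-model prune traces and pooled results plus robustness summaries."""

    models: dict[str, dict]
    filter_log: dict[str, int]
    n_assemblages: dict[str, int]
    pca_variance_fractions: list[float]
    moran: dict | None
    sar: dict | None
    null_comparison: pd.DataFrame | None
    seeds: dict[str, int]

    def to_json_dict(self) -> dict:
        def conv(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            return o

        return conv(
            {
                "models": self.models,
                "filter_log": self.filter_log,
                "n_assemblages": self.n_assemblages,
                "pca_variance_fractions": self.pca_variance_fractions,
                "moran": self.moran,
                "sar": self.sar,
                "null_comparison": self.null_comparison,
                "seeds": self.seeds,
            }
        )


def compute_r_squared(fit: SemFit, outcome: str = "seed") -> float:
    """Variance explained for an endogenous outcome: 1 - psi / implied var."""
    model = fit.model
    if outcome in model.exogenous:
        raise ValueError(f"{outcome!r} is exogenous; R^2 undefined")
    i = model.index(outcome)
    _, Psi = model.build_matrices(fit.theta)
    return float(1.0 - Psi[i, i] / fit.implied[i, i])


def _assemblage_tables(
    bundle: LandscapeBundle,
    cell_size: float,
    filters: FilterRules,
    mega_threshold: float,
) -> tuple[list[pd.DataFrame], pd.DataFrame, Grid, dict, list[float], object]:
    """Replicate-specific filtered assemblage tables plus shared structure."""
    xmin, ymin, xmax, ymax = bundle.landmask.bounds
    grid = build_grid((xmin, ymin, xmax, ymax), cell_size, bundle.landmask)
    logger.info("grid: %d cells (%d x %d)", grid.n_cells, grid.n_rows, grid.n_cols)

    plant_presence = rasterize_points(
        bundle.occurrences, grid, species=list(bundle.plants["species"])
    )
    extant = {
        s: g for s, g in bundle.ranges.items()
        if s in set(bundle.frugivores.loc[bundle.frugivores.status == "extant", "species"])
    }
    extinct = {
        s: g for s, g in bundle.ranges.items()
        if s in set(bundle.frugivores.loc[bundle.frugivores.status == "extinct", "species"])
    }
    extant_presence = rasterize_ranges(extant, grid, guild="extant frugivore")
    extinct_presence = rasterize_ranges(extinct, grid, guild="extinct frugivore")

    foot = summarize_raster(bundle.footprint, grid)
    env = pd.DataFrame(
        {name: summarize_raster(r, grid) for name, r in bundle.env_rasters.items()}
    )
    valid_env = env.notna().all(axis=1).to_numpy() & ~np.isnan(foot)
    env_valid = env.loc[valid_env]
    pca_res = pca(env_valid, k=2)
    pc_scores = np.full((grid.n_cells, 2), np.nan)
    pc_scores[valid_env] = pca_res.scores

    reps = bundle.imputations or [bundle.plants]
    tables = []
    filter_log: dict[str, int] = {}
    base = None
    for k, rep in enumerate(reps):
        metrics = assemblage_metrics(
            grid, plant_presence, rep, extant_presence, extinct_presence,
            bundle.frugivores,
        )
        metrics["footprint"] = foot
        metrics["pc1"] = pc_scores[:, 0]
        metrics["pc2"] = pc_scores[:, 1]
        usable = metrics.dropna(subset=["seed", "mass_extant", "mass_extinct",
                                        "footprint", "pc1", "pc2"])
        filtered, log = filter_assemblages(usable, filters)
        tables.append(filtered)
        if k == 0:
            filter_log = log
            base = filtered
    # replicates share presence and filters, so the kept cell set is identical
    mega_flags = classify_mega_seeded(bundle.plants, mega_threshold)
    mega_flags.index = bundle.plants["species"]
    return tables, base, grid, filter_log, list(pca_res.variance_fractions), (
        plant_presence, mega_flags)


def _fit_model_set(
    tables: list[pd.DataFrame],
    model: PathModel,
    alpha: float,
    robust: bool,
) -> dict:
    datasets = [
        preprocess_variables(t, variables=MODEL_VARIABLES) for t in tables
    ]
    trace: PruneTrace = prune_stepwise(datasets, model, alpha=alpha, robust=robust)
    # R^2 of the focal outcome from the final model, averaged over replicates
    from .pooling import fit_replicates

    if "seed" in trace.final_model.endogenous:
        fits, _ = fit_replicates(datasets, trace.final_model, robust=False)
        r2 = float(np.mean([compute_r_squared(f, "seed") for f in fits]))
    else:
        r2 = 0.0  # pruning removed every path into the focal outcome
    pooled = trace.final_pooled
    return {
        "final_model": trace.final_model.to_dsl(),
        "prune_steps": trace.steps,
        "criteria": trace.criteria,
        "indices": pooled.indices,
        "r_squared": r2,
        "parameters": pooled.table().to_dict(orient="records"),
        "std_estimate": list(map(float, pooled.std_estimate)),
        "labels": pooled.labels,
        "_trace": trace,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and return a structured report."""
    seeds = {
        "master": config.master_seed,
        "landscape": config.master_seed,
        "permutation": (config.master_seed + 1_000_003) % (2**31 - 1),
        "moran": (config.master_seed + 2_000_003) % (2**31 - 1),
    }
    if config.bundle is not None:
        bundle = config.bundle
    else:
        sim = config.simulate
        if sim.rng_seed != config.master_seed:
            sim = SimConfig(**{**sim.__dict__, "rng_seed": config.master_seed})
        bundle = simulate_landscape(sim)

    tables, base, grid, filter_log, pca_fracs, (plant_presence, mega_flags) = (
        _assemblage_tables(bundle, config.cell_size, config.filters,
                           config.mega_threshold)
    )
    if base is None or base.empty:
        raise RuntimeError("stage assemblage: no assemblages pass the filters")

    mega_tables, nonmega_tables = [], []
    for t in tables:
        mg, nm = split_by_mega(t, plant_presence, mega_flags)
        mega_tables.append(mg)
        nonmega_tables.append(nm)
    n_assemblages = {
        "h1_full": len(tables[0]),
        "h2_mega": len(mega_tables[0]),
        "h2_nonmega": len(nonmega_tables[0]),
    }
    logger.info("assemblages: %s", n_assemblages)

    model = config.model or default_downsizing_model()
    models: dict[str, dict] = {}
    for name, tset in (
        ("h1_full", tables),
        ("h2_mega", mega_tables),
        ("h2_nonmega", nonmega_tables),
    ):
        if len(tset[0]) < config.min_rows:
            models[name] = {"skipped": True,
                            "reason": f"only {len(tset[0])} assemblages"}
            logger.warning("model %s skipped (%d rows)", name, len(tset[0]))
            continue
        try:
            models[name] = _fit_model_set(tset, model, config.alpha, config.robust)
        except Exception as exc:  # propagate with stage context
            raise RuntimeError(f"stage sem[{name}]: {exc}") from exc

    null_cmp = None
    if config.run_permutation and "final_model" in models.get("h1_full", {}):
        final = models["h1_full"]["_trace"].final_model
        nd = permutation_null(
            tables[0], final, n_perm=config.n_perm, seed=seeds["permutation"]
        )
        null_cmp = nd.table()

    moran_res = sar_res = None
    if config.run_spatial:
        w = build_weights(base, grid, scheme="queen", row_standardize=True)
        moran_res = morans_i(
            base["seed"].to_numpy(), w, n_perm=999, seed=seeds["moran"]
        )
        sem0 = preprocess_variables(base, variables=MODEL_VARIABLES)
        X = sem0.raw[:, [1, 2, 3, 4, 5]]
        sar = fit_sar_error(sem0.raw[:, 0], X, w)
        sar_res = {
            "lambda": sar["lambda"],
            "loglik": sar["loglik"],
            "terms": ["intercept"] + MODEL_VARIABLES[1:],
            "beta": list(map(float, sar["beta"])),
            "p": list(map(float, sar["p"])),
        }

    for mdl in models.values():
        mdl.pop("_trace", None)
    return RunReport(
        models=models,
        filter_log=filter_log,
        n_assemblages=n_assemblages,
        pca_variance_fractions=pca_fracs,
        moran=moran_res,
        sar=sar_res,
        null_comparison=null_cmp,
        seeds=seeds,
    )


def write_report(report: RunReport, outdir: str | Path) -> None:
    """Serialize a run report as JSON plus a short human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)
    lines = ["# seedpath run report", ""]
    lines.append(f"Assemblages: {report.n_assemblages}")
    fr = report.pca_variance_fractions
    lines.append(f"PC1/PC2 variance fractions: {fr[0]:.3f} / {fr[1]:.3f}")
    for name, mdl in report.models.items():
        if mdl.get("skipped"):
            lines.append(f"\n## {name}: skipped ({mdl['reason']})")
            continue
        lines.append(f"\n## {name}")
        lines.append(f"R^2 (max seed width): {mdl['r_squared']:.3f}")
        lines.append(f"fit: {mdl['indices']}")
        lines.append(f"criteria: {mdl['criteria']}")
        lines.append(f"final model:\n```\n{mdl['final_model']}```")
    if report.moran:
        lines.append(f"\nMoran's I: {report.moran}")
    if report.sar:
        lines.append(f"SAR lambda: {report.sar['lambda']:.3f}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
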