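"""End-to-end pipeline: trends -> lag scan -> averaging -> projection."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .environment import enumerate_lag_grid
from .io import RunConfig, pop_meta_frame, read_environment, read_populations, read_traits
from .lag_models import (
    build_design,
    influence_screen,
    lag_support_profile,
    make_subsets,
    retain_and_average,
    scan_lags,
)
from .projection import project_index
from .trends import compute_trends, filter_eligible

log = logging.getLogger("ecolag")

__all__ = ["run_pipeline"]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by a RunConfig.

    Stages: eligibility filter -> preprocessing/interpolation -> lambda-bar ->
    adjusted-R^2 quality filter -> (optional) influence screen -> lag scan per
    structure and subset -> retention/averaging -> lag-support profiles ->
    scenario projection. Writes result tables and a machine-readable manifest
    (seed, version, per-stage counts) to the output directory and returns the
    result bundle.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "counts": {}, "stages": []}
    bundle: dict = {"manifest": manifest}

    def stage(name: str) -> None:
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("read")
        series = read_populations(config.populations_csv)
        series = [s for s in series if s.taxon_class == config.taxon_class]
        historical, scenario_env = read_environment(config.environment_csv)
        traits = read_traits(config.traits_csv)
        manifest["counts"]["populations_read"] = len(series)

        stage("trends")
        for s in series:
            if not filter_eligible(s):
                log.info("excluded %s: span/points rule", s.population_id)
        trends, counts = compute_trends(series)
        manifest["counts"].update(counts)
        trends.to_csv(out_dir / "trends.csv")
        bundle["trends"] = trends

        kept = set(trends.index)
        series = [s for s in series if s.population_id in kept]
        pop_meta = pop_meta_frame(series)
        gen_lengths = (
            traits["generation_length"].to_dict() if "generation_length" in traits else None
        )

        grid = enumerate_lag_grid(
            config.taxon_class,
            currencies=tuple(config.currencies),
            max_year_lag=config.max_year_lag,
        )
        manifest["counts"]["lag_grid_size"] = len(grid)

        stage("scan")
        scans: dict = {}
        averaged_rows = []
        scan_tables = []
        for dim in config.subset_dimensions:
            subsets = make_subsets(pop_meta, traits, dim)
            for label, ids in subsets.items():
                sub_series = [s for s in series if s.population_id in set(ids)]
                sub_meta = pop_meta.loc[pop_meta.index.isin(ids)]
                for structure in config.structures:
                    model_set = scan_lags(
                        sub_series,
                        historical,
                        sub_meta,
                        trends,
                        traits,
                        structure,
                        grid,
                        gen_lengths,
                    )
                    key = (structure, dim, label)
                    scans[key] = model_set
                    tab = model_set.table.copy()
                    tab.insert(0, "subset", label)
                    tab.insert(0, "dimension", dim)
                    scan_tables.append(tab)
                    avg, avg_se = retain_and_average(model_set)
                    for term, val in avg.items():
                        averaged_rows.append(
                            {
                                "class": config.taxon_class,
                                "structure": structure,
                                "dimension": dim,
                                "subset": label,
                                "term": term,
                                "estimate": val,
                                "se": avg_se[term],
                            }
                        )
        scan_table = pd.concat(scan_tables, ignore_index=True)
        scan_table.to_csv(out_dir / "scan.csv", index=False)
        averaged = pd.DataFrame(averaged_rows)
        averaged.to_csv(out_dir / "averaged_coefficients.csv", index=False)
        bundle["scans"] = scans
        bundle["averaged"] = averaged
        manifest["counts"]["models_fitted"] = int(len(scan_table))

        stage("lag_support")
        profiles = []
        for (structure, dim, label), model_set in scans.items():
            for driver in ("cc", "luc"):
                prof = lag_support_profile(model_set, driver)
                for lag_val, w in prof.items():
                    profiles.append(
                        {
                            "structure": structure,
                            "dimension": dim,
                            "subset": label,
                            "driver": driver,
                            "lag": lag_val,
                            "summed_weight": w,
                        }
                    )
        pd.DataFrame(profiles).to_csv(out_dir / "lag_support.csv", index=False)

        if config.run_influence_screen:
            stage("influence_screen")
            # Screen on the primary (first) structure over all populations at
            # the best lag of the all-populations scan.
            structure = config.structures[0]
            key = (structure, "all", "all") if (structure, "all", "all") in scans else next(iter(scans))
            model_set = scans[key]
            best = model_set.best
            from .environment import rates_for_lag, rates_frame

            rates = rates_frame(rates_for_lag(series, historical, best.lag, gen_lengths))
            design, _ = build_design(pop_meta, trends, rates, traits, structure)
            scores, flagged = influence_screen(design, structure)
            scores.to_csv(out_dir / "influence.csv")
            manifest["counts"]["influence_flagged"] = len(flagged)
            bundle["influence"] = (scores, flagged)

        if config.run_projection and scenario_env:
            stage("projection")
            structure = config.structures[0]
            key = (structure, "all", "all") if (structure, "all", "all") in scans else next(iter(scans))
            proj = project_index(
                scans[key],
                pop_meta,
                traits,
                {k: v for k, v in scenario_env.items() if k in config.scenarios},
                config.taxon_class,
                generation_lengths=gen_lengths,
            )
            proj.to_csv(out_dir / "projection.csv", index=False)
            bundle["projection"] = proj
    except Exception as err:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["error"] = str(err)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
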