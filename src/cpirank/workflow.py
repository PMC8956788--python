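"""End-to-end orchestration: occurrences in, ranked priorities out.

``run_all`` wires the stages together — ingest, filter, unit building,
rarity, conservation scoring, the priority index, descriptive statistics
and the two classifier fits — writing each stage's table under the
configured output directory plus a machine-readable manifest of record
counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import cpi as cpi_mod
from . import iucn, ml, rarity, stats
from .config import RunConfig, derive_seeds
from .errors import AnalysisError, InputError
from .occurrence import (
    LakeRegistry,
    apply_overrides,
    build_units,
    filter_records,
    load_occurrences,
    records_from_frame,
    reports_to_frame,
)

__all__ = ["run_all", "score_frames"]


def score_frames(
    occurrences: pd.DataFrame,
    statuses: pd.DataFrame,
    registry: pd.DataFrame | LakeRegistry,
    k: float = 8.0,
    threshold: float = 0.5,
):
    """In-memory pipeline: tables in, classified per-unit results out.

    Runs ingestion, filtering, unit building, rarity, conservation
    scoring, the priority index and classification on data frames,
    returning ``(results, units, filter_reports)``.  Convenient for
    synthetic data and programmatic use; ``run_all`` is the file-based
    equivalent.
    """
    if not isinstance(registry, LakeRegistry):
        registry = LakeRegistry.from_frame(registry)
    records = records_from_frame(occurrences)
    survivors, reports = filter_records(records, registry)
    units = build_units(survivors, registry)
    srr = rarity.species_rarity(units)
    rrw = rarity.unit_rarity(units, srr)
    scores = iucn.conservation_score(units, iucn.load_status_table(statuses))
    results = cpi_mod.compute_cpi(scores, rrw, registry, k=k)
    results = cpi_mod.classify_priority(results, threshold=threshold)
    return results, units, reports

logger = logging.getLogger(__name__)


def _load_overrides(path: str | None) -> dict[int, str] | None:
    if not path:
        return None
    try:
        frame = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read overrides {path}: {exc}") from exc
    return {int(r.record_id): str(r.waterbody) for r in frame.itertuples(index=False)}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns the manifest (also written to ``outdir/manifest.json``).
    Stage failures propagate as package exceptions naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, 4)
    manifest: dict = {"config": {"k": config.k, "threshold": config.threshold,
                                 "seed": config.seed}, "stages": {}}

    # --- ingest and filter -------------------------------------------------
    records = load_occurrences(config.occurrences, delimiter=config.delimiter)
    registry = LakeRegistry.from_csv(config.registry)
    records = apply_overrides(records, _load_overrides(config.overrides))
    survivors, reports = filter_records(records, registry)
    reports_to_frame(reports).to_csv(outdir / "filter_report.csv", index=False)
    manifest["stages"]["raw_records"] = len(records)
    manifest["stages"]["filter"] = [
        {"stage": r.stage_name, "in": r.records_in, "out": r.records_out}
        for r in reports
    ]
    manifest["stages"]["surviving_records"] = len(survivors)

    units = build_units(survivors, registry)
    manifest["stages"]["units"] = len(units)
    manifest["stages"]["countries"] = len({u.country for u in units})
    manifest["stages"]["species"] = len(set().union(*(u.species for u in units))) if units else 0
    if not units:
        raise AnalysisError("no units survive filtering; check inputs")

    # --- rarity, scoring, index -------------------------------------------
    srr = rarity.species_rarity(units)
    rrw = rarity.unit_rarity(units, srr)
    srr.to_csv(outdir / "species_rarity.csv", index=False)
    rrw.to_csv(outdir / "unit_rarity.csv", index=False)

    status = iucn.load_status_table(config.status)
    scores = iucn.conservation_score(units, status)
    scores.to_csv(outdir / "conservation_scores.csv", index=False)

    results = cpi_mod.compute_cpi(scores, rrw, registry, k=config.k)
    results = cpi_mod.classify_priority(results, threshold=config.threshold)
    ranked = cpi_mod.rank_units(results)
    ranked.to_csv(outdir / "results.csv", index=False)
    class_counts = results["priority_class"].value_counts().to_dict()
    manifest["stages"]["priority_classes"] = {
        "high": int(class_counts.get("high", 0)),
        "low": int(class_counts.get("low", 0)),
    }

    # --- descriptive statistics -------------------------------------------
    stats_summary: dict = {}
    if len(results) >= 3:
        corr = stats.correlation_matrix(
            results, ["richness", "cwt", "rrw", "area_km2"]
        )
        corr.to_csv(outdir / "correlations.csv", index=False)
        stats_summary["correlations"] = "correlations.csv"
    else:
        logger.info("fewer than 3 units; skipping correlation matrix")

    if class_counts.get("high", 0) > 0 and class_counts.get("low", 0) > 0:
        comparisons = {}
        for var in ("area_km2", "cwt", "rrw"):
            cmp_res = stats.compare_by_class(results, var)
            comparisons[var] = {
                "W": cmp_res.statistic_w,
                "p_value": cmp_res.p_value,
                "effect_size_r": cmp_res.effect_size_r,
                "n1_low": cmp_res.n1,
                "n2_high": cmp_res.n2,
                "method": cmp_res.method,
            }
        stats_summary["group_comparisons"] = comparisons
    else:
        logger.info("one priority class absent; skipping group comparisons")

    curve = stats.accumulation_curve(
        units, n_permutations=config.n_accumulation_permutations, seed=seeds[0]
    )
    curve.to_frame().to_csv(outdir / "accumulation_curve.csv", index=False)
    stats_summary["accumulation_final_richness"] = float(curve.mean_richness[-1])
    with open(outdir / "stats_summary.json", "w") as fh:
        json.dump(stats_summary, fh, indent=2)

    # --- classifier fits ---------------------------------------------------
    model_status = "skipped"
    if config.run_models:
        try:
            X, y = ml.build_features(results)
            X_tr, X_te, y_tr, y_te = ml.split_data(
                X, y, train_fraction=config.train_fraction, seed=seeds[1]
            )
            rf = ml.fit_random_forest(
                X_tr,
                y_tr,
                n_estimators=config.rf_trees,
                tune_step_factor=config.tune_step_factor,
                improve=config.improve,
                seed=seeds[2],
            )
            gbt = ml.fit_gradient_boosting(
                X_tr, y_tr, n_rounds=config.gbt_rounds, seed=seeds[3]
            )
            report = {}
            for model in (rf, gbt):
                rep = ml.model_report(model, X_te, y_te)
                report[model.name] = rep.to_dict()
                model.importances.to_csv(
                    outdir / f"importance_{model.name}.csv", index=False
                )
                for feat, curve_df in rep.pd_curves.items():
                    curve_df.to_csv(
                        outdir / f"pd_{model.name}_{feat}.csv", index=False
                    )
            with open(outdir / "model_report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            model_status = "fitted"
        except AnalysisError as exc:
            logger.warning("model stage skipped: %s", exc)
            model_status = f"skipped: {exc}"
    manifest["stages"]["models"] = model_status

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
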