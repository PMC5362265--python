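"""Pipeline orchestration: simulate → segment → score → localize → dynamics → chip.

Every stage reads and writes plain files (16-bit TIFF channels, CSV tables,
YAML config) so runs are reproducible and auditable; a provenance JSON records
the config hash, the global seed and the package version. Re-running with an
identical config produces byte-identical numeric outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .synthetic import (KineticParams, SceneParams, derive_seed,
                        simulate_condition, simulate_ct_table,
                        simulate_dilution_series, simulate_timecourse,
                        write_condition)
from .segmentation import (ANCHOR_DEFAULTS, PREY_DEFAULTS, LabeledSpots,
                           SegmentationParams, segment_spots)
from .scoring import pool_replicate, recruitment_score, summarize_condition
from .localization import classify_pair, pair_anchors
from .dynamics import (TimeCourse, classify_stages, fit_exponential_decay,
                       fit_logistic, interval_rates, normalize_levels)
from .chip import fit_standard_curves, relative_occupancy

__all__ = [
    "PipelineError",
    "default_config",
    "load_config",
    "config_hash",
    "validate_manifest",
    "run_pipeline",
]

log = logging.getLogger("pictquant")

MANIFEST_COLUMNS = ("field_id", "condition", "replicate", "timepoint_min",
                    "red_path", "green_path")


class PipelineError(RuntimeError):
    pass


def default_config(seed: int = 0) -> dict:
    """Demo configuration: two conditions differing in recruited fraction."""
    return {
        "seed": int(seed),
        "scene": {"image_shape": [192, 192], "n_cells": 8,
                  "cell_radius_range": [12.0, 16.0]},
        "conditions": {
            "wt_starved": {"recruited_fraction": 0.9},
            "wt_rich": {"recruited_fraction": 0.1},
        },
        "n_replicates": 3,
        "n_fields": 4,
        "segmentation": {"anchor": {}, "prey": {"gauss_sigma": 1.5}},
        "scoring": {"area_mode": "overlap", "reference": "wt_starved",
                    "compare": "wt_rich"},
        "localization": {"d_min": 1.0, "d_max": 4.0, "margin": 0.15},
        "dynamics": {"slow_threshold": 0.2, "kinetics": {}},
        "chip": {
            "target": "35S_promoter",
            "reference_condition": "wt_rich",
            "occupancy": {"wt_rich": {"35S_promoter": 8.0, "18S": 6.0,
                                      "25S": 6.0, "5S": 4.0},
                          "wt_starved": {"35S_promoter": 1.2, "18S": 1.1,
                                         "25S": 1.1, "5S": 4.0}},
            "efficiency": 1.0, "ct_sd": 0.15,
        },
        "log_level": "INFO",
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    problems = []
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        problems.append("seed must be an integer")
    if "conditions" in cfg and not isinstance(cfg["conditions"], dict):
        problems.append("conditions must map names to SceneParams overrides")
    for key in ("scene", "segmentation", "scoring", "localization",
                "dynamics", "chip"):
        if key in cfg and not isinstance(cfg[key], dict):
            problems.append(f"{key} must be a mapping")
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _scene_params(cfg: dict, overrides: dict | None = None) -> SceneParams:
    kw = dict(cfg.get("scene", {}))
    kw.update(overrides or {})
    for key in ("image_shape", "cell_radius_range"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return SceneParams(**kw)


def _seg_params(cfg: dict, channel: str) -> SegmentationParams:
    base = ANCHOR_DEFAULTS if channel == "anchor" else PREY_DEFAULTS
    return replace(base, **cfg.get("segmentation", {}).get(channel, {}))


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def validate_manifest(path) -> tuple[pd.DataFrame, list[str]]:
    """Load a manifest CSV and return (frame, list of all violations)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise PipelineError(f"cannot read manifest {path}: {exc}") from exc
    violations: list[str] = []
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        return df, [f"manifest lacks columns: {missing}"]
    dupes = df["field_id"][df["field_id"].duplicated()].unique().tolist()
    if dupes:
        violations.append(f"duplicate field ids: {dupes}")
    base = path.parent
    for _, row in df.iterrows():
        rp, gp = base / row["red_path"], base / row["green_path"]
        shapes = []
        for chan, p in (("red", rp), ("green", gp)):
            if not p.exists():
                violations.append(
                    f"field {row['field_id']}: missing {chan} file {p.name}")
            else:
                shapes.append(tifffile.imread(p).shape)
        if len(shapes) == 2 and shapes[0] != shapes[1]:
            violations.append(
                f"field {row['field_id']}: channel shapes differ "
                f"{shapes[0]} vs {shapes[1]}")
    return df, violations


def _load_field_spots(segdir: Path, field_id: str, channel: str,
                      regions: pd.DataFrame) -> LabeledSpots:
    labels = tifffile.imread(segdir / f"{field_id}_{channel}_labels.tif").astype(int)
    sub = regions[(regions["field_id"] == field_id)
                  & (regions["channel"] == channel)]
    table = sub.drop(columns=["field_id", "channel"]).reset_index(drop=True)
    return LabeledSpots(labels, table, channel)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> Path:
    collections = {}
    for cond, overrides in cfg["conditions"].items():
        params = _scene_params(cfg, overrides)
        # str hash must be process-stable for reproducible seeds
        cond_key = int.from_bytes(hashlib.sha256(cond.encode()).digest()[:3],
                                  "big")
        collections[cond] = simulate_condition(
            params, cfg.get("n_replicates", 3), cfg.get("n_fields", 6),
            base_seed=derive_seed(cfg["seed"], cond_key), condition=cond)
    write_condition(outdir, collections)
    log.info("simulate: wrote %d conditions to %s", len(collections), outdir)
    return outdir / "manifest.csv"


def stage_segment(manifest_path: Path, cfg: dict, outdir: Path) -> Path:
    manifest, violations = validate_manifest(manifest_path)
    if violations:
        raise PipelineError("manifest invalid: " + "; ".join(violations))
    outdir.mkdir(parents=True, exist_ok=True)
    anchor_p = _seg_params(cfg, "anchor")
    prey_p = _seg_params(cfg, "prey")
    base = Path(manifest_path).parent
    frames = []
    for _, row in manifest.iterrows():
        red = tifffile.imread(base / row["red_path"]).astype(float)
        green = tifffile.imread(base / row["green_path"]).astype(float)
        for channel, img, p in (("red", red, anchor_p), ("green", green, prey_p)):
            spots = segment_spots(img, img, p, channel)
            tifffile.imwrite(outdir / f"{row['field_id']}_{channel}_labels.tif",
                             spots.labels.astype(np.uint16))
            t = spots.table.copy()
            t.insert(0, "channel", channel)
            t.insert(0, "field_id", row["field_id"])
            frames.append(t)
    regions = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    regions.to_csv(outdir / "regions.csv", index=False)
    log.info("segment: %d fields -> %s", len(manifest), outdir / "regions.csv")
    return outdir / "regions.csv"


def stage_score(manifest_path: Path, segdir: Path, cfg: dict,
                outdir: Path) -> dict[str, Path]:
    manifest = pd.read_csv(manifest_path)
    regions = pd.read_csv(segdir / "regions.csv")
    base = Path(manifest_path).parent
    opts = cfg.get("scoring", {})
    area_mode = opts.get("area_mode", "overlap")
    outdir.mkdir(parents=True, exist_ok=True)

    field_rows, rep_results = [], {}
    for _, row in manifest.iterrows():
        fid = row["field_id"]
        green = tifffile.imread(base / row["green_path"]).astype(float)
        anchors = _load_field_spots(segdir, fid, "red", regions)
        prey = _load_field_spots(segdir, fid, "green", regions)
        res = recruitment_score(green, prey, anchors, area_mode,
                                meta={"field_id": fid})
        if res is None:
            continue
        field_rows.append({"field_id": fid, "condition": row["condition"],
                           "replicate": row["replicate"],
                           "yellow_area": res.yellow_area,
                           "red_area": res.red_area, "score": res.score})
        rep_results.setdefault((row["condition"], row["replicate"]), []).append(res)

    pd.DataFrame(field_rows).to_csv(outdir / "scores_fields.csv", index=False)

    rep_rows = []
    cond_scores: dict[str, list[float]] = {}
    for (cond, rep), results in sorted(rep_results.items()):
        pooled = pool_replicate(results)
        rep_rows.append({"condition": cond, "replicate": rep,
                         "yellow_area": pooled.yellow_area,
                         "red_area": pooled.red_area, "score": pooled.score})
        cond_scores.setdefault(cond, []).append(pooled.score)
    pd.DataFrame(rep_rows).to_csv(outdir / "scores_replicates.csv", index=False)

    summaries = {c: summarize_condition(c, s) for c, s in cond_scores.items()}
    reference = summaries.get(opts.get("reference"))
    compare = opts.get("compare")
    rows = []
    for cond in sorted(summaries):
        comparison = summaries.get(compare) if compare and compare != cond else None
        s = summarize_condition(cond, cond_scores[cond], reference, comparison)
        rows.append(s.to_row())
    pd.DataFrame(rows).to_csv(outdir / "condition_summary.csv", index=False)
    log.info("score: %d conditions -> %s", len(rows), outdir)
    return {"fields": outdir / "scores_fields.csv",
            "replicates": outdir / "scores_replicates.csv",
            "summary": outdir / "condition_summary.csv"}


def stage_localize(manifest_path: Path, segdir: Path, cfg: dict,
                   outdir: Path) -> Path:
    manifest = pd.read_csv(manifest_path)
    regions = pd.read_csv(segdir / "regions.csv")
    base = Path(manifest_path).parent
    opts = cfg.get("localization", {})
    scene = cfg.get("scene", {})
    pixel_size = scene.get("pixel_size", 0.1)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, frow in manifest.iterrows():
        fid = frow["field_id"]
        red = tifffile.imread(base / frow["red_path"]).astype(float)
        green = tifffile.imread(base / frow["green_path"]).astype(float)
        anchors = _load_field_spots(segdir, fid, "red", regions)
        pairs = pair_anchors(anchors, pixel_size, opts.get("d_min", 1.0),
                             opts.get("d_max", 4.0))
        for k, pair in enumerate(pairs):
            pc = classify_pair(red, green, pair, margin=opts.get("margin", 0.15))
            rows.append({"field_id": fid, "pair": k,
                         "row_a": pair.pos_a[0], "col_a": pair.pos_a[1],
                         "row_b": pair.pos_b[0], "col_b": pair.pos_b[1],
                         "separation_um": pair.separation_um,
                         "green_peak_fraction": pc.green_peak_fraction,
                         "class": pc.label, "reason": pc.reason})
    pd.DataFrame(rows, columns=["field_id", "pair", "row_a", "col_a", "row_b",
                                "col_b", "separation_um",
                                "green_peak_fraction", "class", "reason"]
                 ).to_csv(outdir / "localization.csv", index=False)
    log.info("localize: %d anchor pairs -> %s", len(rows), outdir)
    return outdir / "localization.csv"


def analyze_timecourses(courses: dict[str, TimeCourse],
                        slow_threshold: float = 0.2) -> dict:
    """Normalize, differentiate, fit and stage-label a pair of time courses.

    The first course is fitted with the exponential-decay model, the second
    with the logistic; stage labels carry the complex ids.
    """
    ids = list(courses)
    if len(ids) != 2:
        raise ValueError("expected exactly two complexes")
    normalized = {cid: normalize_levels(tc) for cid, tc in courses.items()}
    rates = {cid: interval_rates(tc) for cid, tc in normalized.items()}
    fits = {ids[0]: fit_exponential_decay(normalized[ids[0]]),
            ids[1]: fit_logistic(normalized[ids[1]])}
    stages = classify_stages(rates[ids[0]], rates[ids[1]], slow_threshold,
                             label_a=f"{ids[0]}_fast", label_b=f"{ids[1]}_fast")
    return {"normalized": normalized, "rates": rates, "fits": fits,
            "stages": stages}


def stage_dynamics(cfg: dict, outdir: Path,
                   timecourse_csv: Path | None = None) -> Path:
    opts = cfg.get("dynamics", {})
    outdir.mkdir(parents=True, exist_ok=True)
    if timecourse_csv is not None:
        df = pd.read_csv(timecourse_csv)
        courses = {cid: TimeCourse(cid, sub["timepoint_min"].to_numpy(),
                                   sub["level"].to_numpy())
                   for cid, sub in df.groupby("complex", sort=False)}
    else:
        kp = KineticParams(**opts.get("kinetics", {}))
        courses = simulate_timecourse(kp, seed=derive_seed(cfg["seed"], 7001))
        pd.concat([
            pd.DataFrame({"complex": cid, "timepoint_min": tc.timepoints,
                          "level": tc.levels}) for cid, tc in courses.items()
        ], ignore_index=True).to_csv(outdir / "timecourse.csv", index=False)
    res = analyze_timecourses(courses, opts.get("slow_threshold", 0.2))

    pd.concat([
        pd.DataFrame({"complex": cid, "timepoint_min": tc.timepoints,
                      "level_normalized": tc.levels})
        for cid, tc in res["normalized"].items()
    ], ignore_index=True).to_csv(outdir / "normalized.csv", index=False)
    pd.concat([
        pd.DataFrame({"complex": cid, "midpoint_min": rs.midpoints,
                      "rate_per_min": rs.rates})
        for cid, rs in res["rates"].items()
    ], ignore_index=True).to_csv(outdir / "rates.csv", index=False)
    with open(outdir / "fits.json", "w") as fh:
        json.dump({cid: {"model": f.model, "params": f.params, "rss": f.rss,
                         "converged": f.converged, "degenerate": f.degenerate}
                   for cid, f in res["fits"].items()}, fh, indent=2)
    pd.DataFrame(res["stages"].segments,
                 columns=["t_start_min", "t_end_min", "stage"]
                 ).to_csv(outdir / "stages.csv", index=False)
    log.info("dynamics: %d stages -> %s", len(res["stages"].segments), outdir)
    return outdir / "stages.csv"


def stage_chip(cfg: dict, outdir: Path) -> Path:
    opts = cfg.get("chip", {})
    outdir.mkdir(parents=True, exist_ok=True)
    occ_truth = {(cond, locus): v
                 for cond, loci in opts.get("occupancy", {}).items()
                 for locus, v in loci.items()}
    conditions = sorted({c for c, _ in occ_truth}) or ["wt_rich"]
    eff = opts.get("efficiency", 1.0)
    dil = simulate_dilution_series(efficiency=eff, ct_sd=opts.get("ct_sd", 0.15),
                                   seed=derive_seed(cfg["seed"], 8001))
    cts = simulate_ct_table(occ_truth, conditions, efficiency=eff,
                            ct_sd=opts.get("ct_sd", 0.15),
                            seed=derive_seed(cfg["seed"], 8002))
    dil.to_csv(outdir / "dilutions.csv", index=False)
    cts.to_csv(outdir / "ct_table.csv", index=False)
    curves = fit_standard_curves(dil)
    result = relative_occupancy(cts, curves, opts.get("target", "35S_promoter"),
                                reference_condition=opts.get("reference_condition"))
    pd.DataFrame([{"amplicon": c.amplicon, "slope": c.slope,
                   "intercept": c.intercept, "efficiency": c.efficiency,
                   "r_squared": c.r_squared} for c in curves.values()]
                 ).to_csv(outdir / "standard_curves.csv", index=False)
    result.summary.to_csv(outdir / "occupancy.csv", index=False)
    log.info("chip: %d conditions -> %s", len(result.summary), outdir)
    return outdir / "occupancy.csv"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, outdir) -> dict:
    """Run all stages in dependency order; outputs carry full provenance."""
    _validate_config(cfg)
    cfg = copy.deepcopy(cfg)
    cfg.setdefault("seed", 0)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.get("log_level", "INFO"))

    provenance = {"config_hash": config_hash(cfg), "seed": cfg["seed"],
                  "version": __version__, "config": cfg}
    stage = "simulate"
    try:
        manifest = stage_simulate(cfg, outdir / "simulate")
        stage = "segment"
        stage_segment(manifest, cfg, outdir / "segment")
        stage = "score"
        score_paths = stage_score(manifest, outdir / "segment", cfg,
                                  outdir / "score")
        stage = "localize"
        loc = stage_localize(manifest, outdir / "segment", cfg,
                             outdir / "localize")
        stage = "dynamics"
        dyn = stage_dynamics(cfg, outdir / "dynamics")
        stage = "chip"
        chip_out = stage_chip(cfg, outdir / "chip")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return {"manifest": manifest, **score_paths, "localization": loc,
            "dynamics": dyn, "chip": chip_out,
            "provenance": outdir / "provenance.json"}
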