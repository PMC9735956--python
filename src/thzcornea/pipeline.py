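"""End-to-end orchestration of the four pipeline stages.

Stage functions take a :class:`~thzcornea.config.RunConfig` plus file
paths and write self-describing artifacts (config hash and seed in every
output).  ``run_all`` chains simulate -> process -> features ->
classify into one output directory; with a fixed master seed the whole
chain is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, archive
from .classify import correlation_report, evaluate_predictor_set
from .config import RunConfig, config_hash, config_to_dict
from .features import feature_table
from .processing import process_archive
from .simulate import generate_cohort

__all__ = ["run_simulate", "run_process", "run_features", "run_classify", "run_all"]

log = logging.getLogger("thzcornea")


def _ensure_outdir(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        if not path.parent.exists():
            raise FileNotFoundError(
                f"output directory {path} cannot be created: parent {path.parent} does not exist"
            )
        path.mkdir()
    return path


def run_simulate(cfg: RunConfig, outdir, seed: Optional[int] = None) -> dict:
    """Generate the cohort; write archive.h5, labels.csv and manifest.json."""
    outdir = _ensure_outdir(Path(outdir))
    seed = cfg.seed if seed is None else int(seed)
    chash = config_hash(cfg)
    t0 = time.perf_counter()
    cohort = generate_cohort(cfg.simulate, seed=seed)
    log.info("simulate: %d samples in groups %s", len(cohort.samples), dict(cfg.simulate.group_sizes))
    archive_path = outdir / "archive.h5"
    labels_path = outdir / "labels.csv"
    cohort.write(archive_path, labels_path, meta={"config_hash": chash, "seed": seed})
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": chash,
        "config": config_to_dict(cfg),
        "outputs": {"archive": archive_path.name, "labels": labels_path.name},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    log.info("simulate: wrote %s in %.1f s", archive_path, time.perf_counter() - t0)
    return {"archive": archive_path, "labels": labels_path, "manifest": outdir / "manifest.json"}


def run_process(cfg: RunConfig, archive_path, out_csv) -> pd.DataFrame:
    """Per-pixel slope table from a scan archive."""
    t0 = time.perf_counter()
    table = process_archive(
        archive_path,
        band=cfg.process.band,
        cutoff_thz=cfg.process.cutoff_thz,
        regularization=cfg.process.regularization,
        out_csv=out_csv,
        config_hash=config_hash(cfg),
    )
    log.info("process: %d slope rows in %.1f s", len(table), time.perf_counter() - t0)
    return table


def run_features(cfg: RunConfig, slopes_csv, labels_csv, out_csv) -> pd.DataFrame:
    """Per-sample S_Start/S_Elev/S_Phys table joined with labels."""
    slopes = archive.read_table_csv(slopes_csv)
    labels = archive.read_labels_csv(labels_csv)
    table = feature_table(
        slopes, cfg.simulate.protocol, labels=labels, window_min=cfg.features.window_min
    )
    archive.write_table_csv(table, out_csv, config_hash=config_hash(cfg))
    log.info("features: %d samples", len(table))
    return table


def run_classify(cfg: RunConfig, features_csv, outdir, seed: Optional[int] = None) -> dict:
    """Evaluate every configured predictor set; write JSON + AUC CSVs."""
    outdir = _ensure_outdir(Path(outdir))
    features = archive.read_table_csv(features_csv)
    chash = config_hash(cfg)
    eval_cfg = cfg.classify.evaluation
    if seed is not None:
        eval_cfg = replace(eval_cfg, seed=int(seed))
    results = {}
    for predictors in cfg.classify.predictor_sets:
        t0 = time.perf_counter()
        res = evaluate_predictor_set(features, predictors, eval_cfg)
        name = res.predictor_set
        slug = name.replace("+", "_").lower()
        payload = res.to_dict()
        payload["config_hash"] = chash
        with open(outdir / f"{slug}.json", "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)
        archive.write_table_csv(
            pd.DataFrame({"iteration": range(res.n_iterations), "auc": res.aucs}),
            outdir / f"{slug}_aucs.csv",
            config_hash=chash,
        )
        log.info(
            "classify %s: AUC %.3f +/- %.3f (%.1f s)",
            name, res.auc_mean, res.auc_std, time.perf_counter() - t0,
        )
        results[name] = res
    try:
        corr = correlation_report(features)
        with open(outdir / "correlation.json", "w") as fh:
            json.dump(
                {
                    "slope": corr.slope,
                    "intercept": corr.intercept,
                    "r_squared": corr.r_squared,
                    "n": corr.n,
                    "config_hash": chash,
                },
                fh, sort_keys=True, indent=1,
            )
    except ValueError as exc:  # degenerate features: report omitted, not fatal
        log.warning("correlation report skipped: %s", exc)
    return results


def run_all(cfg: RunConfig, outdir, seed: Optional[int] = None) -> dict:
    """simulate -> process -> features -> classify into one directory."""
    outdir = _ensure_outdir(Path(outdir))
    seed = cfg.seed if seed is None else int(seed)
    cfg = replace(cfg, seed=seed)
    paths = run_simulate(cfg, outdir, seed=seed)
    slopes_csv = outdir / "slopes.csv"
    run_process(cfg, paths["archive"], slopes_csv)
    features_csv = outdir / "features.csv"
    run_features(cfg, slopes_csv, paths["labels"], features_csv)
    results = run_classify(cfg, features_csv, outdir / "results", seed=seed)
    return {
        "outdir": outdir,
        "archive": paths["archive"],
        "labels": paths["labels"],
        "slopes": slopes_csv,
        "features": features_csv,
        "results_dir": outdir / "results",
        "results": results,
    }
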