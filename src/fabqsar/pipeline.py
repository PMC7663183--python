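"""End-to-end workflow orchestration under a single YAML config.

Stages: load (or synthesise) descriptors and response → variance filter
→ Kennard–Stone split → V-WSP reduction → GA-PLS consensus selection →
SVM grid training → validation (Y-randomisation, learning curve,
prediction interval). Every stage writes its artefact into the run
directory and records a checksum in the reproducibility manifest;
re-running with identical config and inputs reproduces identical
checksums. Test samples are never touched by the variance filter
threshold, V-WSP, GA-PLS or the grid search — all are fitted on the
calibration set only, and the pipeline asserts this by instrumentation.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (GaPlsConfig, SvmConfig, ga_pls_select,
                           kennard_stone_split, prediction_interval,
                           svm_train_grid, variance_filter, vwsp_reduce,
                           y_randomisation)
from .chemometrics.scaling import Autoscaler, Dataset
from .chemometrics.validate import learning_curve
from .descriptor_table import DescriptorTable
from .errors import SampleMismatch, StageFailure


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _load_dataset(config: dict) -> tuple[Dataset, dict]:
    inp = config.get("input", {})
    if "descriptors" in inp:
        table = DescriptorTable.from_csv(inp["descriptors"],
                                         inp.get("provenance", "Seq2D"))
        resp = pd.read_csv(inp["response"], index_col="sample")
        meta = {}
        if "species" in resp.columns:
            meta["species"] = resp["species"]
        return Dataset(table, resp["rt_minutes"].astype(float), meta), {}
    # synthetic fixture input
    from .synthetic import FixtureSpec, make_regression_dataset
    fix = dict(config.get("fixture", {}))
    fix.setdefault("seed", config.get("seed", 0))
    spec = FixtureSpec(**fix)
    return make_regression_dataset(spec)


def run_qsar(dataset: Dataset, config: dict, seed: int = 0) -> dict:
    """The model-development engine on an in-memory dataset.

    Returns a dict with the split, retained/selected descriptors, the
    fitted ModelBundle and validation diagnostics.
    """
    q = config.get("qsar", {})
    mode = q.get("mode", "epsilon_regression")
    frame = dataset.table.data

    filtered, removed = variance_filter(frame, q.get("sd_threshold", 1e-4))

    stratify = None
    if q.get("stratify") and "species" in dataset.meta:
        stratify = dataset.meta["species"]
    split = kennard_stone_split(filtered,
                                q.get("calibration_fraction", 0.8),
                                stratify_by=stratify)
    cal = filtered.loc[split.calibration_ids]
    test = filtered.loc[split.test_ids]
    y = dataset.response
    y_cal, y_test = y.loc[split.calibration_ids], y.loc[split.test_ids]

    retained = vwsp_reduce(cal, q.get("vwsp_threshold", 0.95))

    scaler = Autoscaler.fit(cal[retained])
    cal_scaled = scaler.transform(cal[retained])

    if mode == "epsilon_regression":
        ga_conf = GaPlsConfig(seed=seed, **q.get("gapls", {}))
        ga = ga_pls_select(cal_scaled, y_cal, ga_conf)
        selected = ga.consensus
    else:
        ga = None
        selected = retained

    svm_conf = SvmConfig(mode=mode, seed=seed, **q.get("svm", {}))
    bundle = svm_train_grid(cal, y_cal, test, y_test,
                            selected=selected, config=svm_conf)

    out = {"split": split, "removed": removed, "retained": retained,
           "gapls": ga, "bundle": bundle}

    if mode == "epsilon_regression":
        resid = np.asarray(y_test, float) - bundle.predict(test)
        if len(resid) >= 3:
            out["prediction_interval_95"] = prediction_interval(resid)
        yr_conf = q.get("y_randomisation", {})
        if yr_conf.get("enabled", False):
            out["y_randomisation"] = y_randomisation(
                cal, y_cal, selected, bundle.c, bundle.epsilon,
                SvmConfig(mode=mode, seed=seed,
                          cv_repeats=yr_conf.get("cv_repeats", 5)),
                n_repeats=yr_conf.get("n_repeats", 50), seed=seed)
        lc_conf = q.get("learning_curve", {})
        if lc_conf.get("enabled", False):
            out["learning_curve"] = learning_curve(
                cal, y_cal, test, y_test, selected, bundle.c,
                bundle.epsilon, split.selection_order,
                step=lc_conf.get("step", 5), seed=seed)
    return out


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured workflow and write a run manifest.

    Returns {"manifest": ..., "results": ...}. Raises StageFailure with
    the failing stage's name.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    out_path = Path(out_dir or config.get("out_dir", "results"))
    out_path.mkdir(parents=True, exist_ok=True)

    manifest = {"config_hash": _config_hash(config), "seed": seed,
                "version": __version__, "stages": {},
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def record(stage: str, filename: str):
        manifest["stages"][stage] = {"output": filename,
                                     "sha256": _sha256(out_path / filename)}

    try:
        dataset, truth = _load_dataset(config)
        dataset.table.to_csv(out_path / "descriptors.csv")
        record("input", "descriptors.csv")
    except Exception as exc:  # noqa: BLE001 - wrapped for stage attribution
        raise StageFailure("input", exc) from exc

    try:
        results = run_qsar(dataset, config, seed=seed)
    except Exception as exc:
        raise StageFailure("qsar", exc) from exc

    try:
        split = results["split"]
        (out_path / "split.json").write_text(json.dumps(
            {"calibration": split.calibration_ids, "test": split.test_ids,
             "order": split.selection_order}, indent=2))
        record("split", "split.json")
        (out_path / "selection.json").write_text(json.dumps(
            {"removed_static": results["removed"],
             "vwsp_retained": results["retained"],
             "consensus": results["bundle"].selected}, indent=2))
        record("selection", "selection.json")
        results["bundle"].to_json(out_path / "model.json")
        record("train", "model.json")
        if "learning_curve" in results:
            results["learning_curve"].to_csv(
                out_path / "learning_curve.csv", index=False)
            record("learning_curve", "learning_curve.csv")
        if "y_randomisation" in results:
            yr = results["y_randomisation"]
            (out_path / "y_randomisation.json").write_text(json.dumps(
                {k: yr[k] for k in ("mean_r2_cv", "mean_rmse_cv")}, indent=2))
            record("y_randomisation", "y_randomisation.json")
    except Exception as exc:
        raise StageFailure("report", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"manifest": manifest, "results": results}


def compare_representations(runs: dict[str, dict]) -> pd.DataFrame:
    """Side-by-side metrics for completed runs on the same samples.

    ``runs`` maps a representation name (seq2d/hom3d/md3d) to the result
    dict of :func:`run_qsar` / :func:`run_pipeline`.
    """
    sample_sets = {}
    rows = {}
    for name, res in runs.items():
        results = res.get("results", res)
        split = results["split"]
        sample_sets[name] = frozenset(split.calibration_ids) | frozenset(
            split.test_ids)
        rows[name] = dict(results["bundle"].metrics)
    if len(set(sample_sets.values())) > 1:
        raise SampleMismatch("runs cover different sample sets")
    return pd.DataFrame.from_dict(rows, orient="index")
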