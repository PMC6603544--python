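"""End-to-end pipeline: simulate, segment, extract, NNI, screen, train, evaluate.

Every stage reads and writes plain CSV/PNG/JSON artifacts on disk, so
any stage can be re-run in isolation or swapped for real data.  A run
manifest records the configuration hash, the seed and a SHA-256 digest
of every output file; re-running with the same configuration and seed
is bit-reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .evaluation import default_stage_map, evaluation_report
from .features import CalibrationScale, GLCMParams, extract_table
from .nitrogen import classify_limiting, critical_n, fit_dilution_curve, nni_table
from .reference import NC_VALUES, growth_table, preset_features, published_nni_table
from .regression import NNIRegressor, feature_importance, split_dataset
from .segmentation import SegmentationParams, segment_plant
from .selection import anova_screen, normalize_features
from .synthetic import AgronomicDesign, generate_dataset

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "make_fixtures"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "treatments": {"CK": 0.0, "T1": 0.134, "T2": 0.163, "T3": 0.191},
        "days": [7, 14, 21, 28, 35, 42],
        "replicates": 16,
        "noise_cv": 0.05,
        "canvas_px": [240, 240],
    },
    "segmentation": {
        "exg_min": 40,
        "exg_max": 200,
        "gray_max": 240,
        "open_kernel_px": 3,
        "min_object_frac": 0.1,
        "max_hole_frac": 0.05,
    },
    "glcm": {"distance": 1, "levels": 256},
    "scale": {"mm_per_px": 1.0},
    "nitrogen": {"alpha": 0.05, "status_tol": 0.005, "reference_treatment": None},
    "selection": {"alpha": 0.05, "preset": None},
    "models": {
        "algorithms": ["rf", "svr", "nn"],
        "train_frac": 0.75,
        "cv": 10,
        "nn_output": "logistic",
        "importance_permutations": 5,
    },
    "evaluation": {"stage_map": None},
}

# sections whose values are free-form mappings, not fixed keys
_FREE_KEYS = {("synthetic", "treatments"), ("evaluation", "stage_map")}


def _validate(config: dict, defaults: dict, path: tuple = ()) -> None:
    for key, value in config.items():
        if key not in defaults:
            raise KeyError(f"unknown config key: {'.'.join(path + (key,))}")
        if isinstance(defaults[key], dict) and (path + (key,)) not in _FREE_KEYS:
            if not isinstance(value, dict):
                raise TypeError(f"config section {key} must be a mapping")
            _validate(value, defaults[key], path + (key,))


def _merge(defaults: dict, overrides: dict, path: tuple = ()) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        if (
            isinstance(value, dict)
            and isinstance(out.get(key), dict)
            and (path + (key,)) not in _FREE_KEYS
        ):
            out[key] = _merge(out[key], value, path + (key,))
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file and/or a dict.

    Unknown keys are rejected before any stage runs.
    """
    config = copy.deepcopy(DEFAULT_CONFIG)
    for source in (path and yaml.safe_load(Path(path).read_text()), overrides):
        if source:
            _validate(source, DEFAULT_CONFIG)
            config = _merge(config, source)
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _canonical_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def compute_sample_nni(records: pd.DataFrame, alpha: float = 0.05,
                       reference_treatment: str | None = None) -> pd.DataFrame:
    """Per-sample NNI via the dilution-curve procedure.

    Classifies treatments as N-limiting from replicate biomass, fits
    the critical-N curve on the N-limiting records, evaluates it at the
    per-date mean biomass of the non-N-limiting treatments (or of
    ``reference_treatment`` if named), and divides each sample's N
    concentration by the date's critical concentration.
    """
    labels = classify_limiting(records, alpha=alpha)
    limiting = [t for t, lab in labels["overall"].items() if lab == "N-limiting"]
    doses = records.groupby("treatment")["dose"].first().sort_values()
    if not limiting:  # fall back to all but the top dose
        limiting = list(doses.index[:-1])
    # fit on the highest-dose N-limiting treatment: the one closest to the
    # critical boundary, whose N concentration tracks Nc most closely
    fit_trt = max(limiting, key=lambda t: doses[t])
    lim = records[records["treatment"] == fit_trt]
    curve = fit_dilution_curve(lim["biomass_dm"], lim["n_conc"])
    if reference_treatment is not None:
        ref = records[records["treatment"] == reference_treatment]
    else:
        ref = records[~records["treatment"].isin(limiting)]
    dm_ref = ref.groupby("day")["biomass_dm"].mean()
    out = records.copy()
    out["nc"] = [critical_n(curve, dm_ref[d]) for d in out["day"]]
    out["nni"] = out["n_conc"] / out["nc"]
    out.attrs["curve"] = curve
    return out


def run_pipeline(config: dict | None = None, out_dir="pipeline_run") -> dict:
    """Execute every stage and return the run manifest."""
    config = config or load_config()
    _validate(config, DEFAULT_CONFIG)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"version": __version__, "seed": seed, "config": config,
                      "stages": {}}

    def record_stage(name: str, *paths: Path) -> None:
        manifest["stages"][name] = {
            "outputs": {p.name: _sha256(p) for p in paths}
        }

    # --- simulate -----------------------------------------------------
    syn = config["synthetic"]
    design = AgronomicDesign(
        treatments=dict(syn["treatments"]), days=tuple(syn["days"]),
        replicates=int(syn["replicates"]), seed=seed,
    )
    truth = generate_dataset(design, out_dir, canvas_px=tuple(syn["canvas_px"]),
                             noise_cv=float(syn["noise_cv"]))
    record_stage("simulate", out_dir / "truth.csv")

    # --- segment ------------------------------------------------------
    seg_params = SegmentationParams(**config["segmentation"])
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(exist_ok=True)
    masks = []
    for _, rec in truth.iterrows():
        image = np.asarray(Image.open(out_dir / rec["image_path"]).convert("RGB"))
        mask = segment_plant(image, seg_params)
        Image.fromarray((mask * 255).astype(np.uint8)).save(
            mask_dir / f"{rec['sample_id']}.png"
        )
        masks.append((image, mask))
    record_stage("segment")

    # --- extract ------------------------------------------------------
    glcm = GLCMParams(**config["glcm"])
    scale = CalibrationScale(**config["scale"])
    images, mask_arrays = zip(*masks)
    features = extract_table(images, mask_arrays, sample_ids=truth["sample_id"],
                             glcm=glcm, scale=scale)
    features.to_csv(out_dir / "features.csv", index=False)
    record_stage("extract", out_dir / "features.csv")

    # --- nni ----------------------------------------------------------
    nit = config["nitrogen"]
    nni_df = compute_sample_nni(truth, alpha=float(nit["alpha"]),
                                reference_treatment=nit["reference_treatment"])
    nni_out = nni_df[["sample_id", "treatment", "day", "n_conc", "nc", "nni"]]
    nni_out.to_csv(out_dir / "nni.csv", index=False)
    record_stage("nni", out_dir / "nni.csv")

    # --- select -------------------------------------------------------
    sel = config["selection"]
    feat_only = features.drop(columns="sample_id")
    if sel["preset"]:
        selected = preset_features(sel["preset"])
        screening = {"preset": sel["preset"], "selected": selected}
    else:
        norm = normalize_features(feat_only)
        result = anova_screen(norm, truth["treatment"], truth["day"],
                              alpha=float(sel["alpha"]))
        selected = result.selected
        screening = {
            "alpha": result.alpha,
            "selected": selected,
            "p_matrix": {str(d): result.p_matrix[d].round(12).to_dict()
                         for d in result.p_matrix.columns},
        }
    (out_dir / "screening.json").write_text(json.dumps(screening, indent=2))
    record_stage("select", out_dir / "screening.json")
    if not selected:
        raise RuntimeError("select stage: no features passed the all-dates rule")

    # --- train + predict ---------------------------------------------
    mdl = config["models"]
    data = features.merge(nni_out[["sample_id", "treatment", "day", "nni"]],
                          on="sample_id")
    train, test = split_dataset(data, train_frac=float(mdl["train_frac"]),
                                seed=seed)
    predictions = {}
    cv_summary = {}
    model_paths = []
    for algo in mdl["algorithms"]:
        est = NNIRegressor(algorithm=algo, cv=int(mdl["cv"]), random_state=seed,
                           nn_output=mdl["nn_output"])
        est.fit(train[selected], train["nni"])
        pred = est.predict(test[selected])
        preds = pd.DataFrame({
            "sample_id": test["sample_id"].to_numpy(),
            "day": test["day"].to_numpy(),
            "treatment": test["treatment"].to_numpy(),
            "measured_nni": test["nni"].to_numpy(),
            "simulated_nni": pred,
        })
        path = out_dir / f"predictions_{algo}.csv"
        preds.to_csv(path, index=False)
        predictions[algo] = preds
        cv = est.cv_result_
        cv_summary[algo] = {
            "best_params": cv.best_params,
            "cv_rmse_mean": float(cv.mean_rmse[cv.best_index]),
            "cv_rmse_sd": float(cv.sd_rmse[cv.best_index]),
        }
        imp = feature_importance(est, test[selected], test["nni"],
                                 n_permutations=int(mdl["importance_permutations"]),
                                 seed=seed)
        imp_path = out_dir / f"importance_{algo}.csv"
        imp.scores.rename("pct_inc_mse").to_csv(imp_path)
        model_paths += [path, imp_path]
    (out_dir / "cv_summary.json").write_text(json.dumps(cv_summary, indent=2))
    record_stage("train", out_dir / "cv_summary.json", *model_paths)

    # --- evaluate -----------------------------------------------------
    stage_map = config["evaluation"]["stage_map"]
    if stage_map is not None:
        stage_map = {int(k): v for k, v in stage_map.items()}
    else:
        stage_map = default_stage_map(data["day"])
    report = evaluation_report(predictions, stage_map)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    record_stage("evaluate", out_dir / "report.json")

    manifest["manifest_hash"] = _canonical_hash(
        {k: manifest[k] for k in ("version", "seed", "config", "stages")}
    )
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures(out_dir) -> dict:
    """Write the bundled reference tables as machine-readable fixtures.

    Produces ``growth.csv`` (per-treatment biomass and N concentration
    summaries), ``nc.csv`` (per-date critical N concentrations),
    ``expected_nni.csv`` (the published NNI table) and ``preset23.txt``
    (the published 23-feature screening result).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    growth = growth_table()
    growth.to_csv(out_dir / "growth.csv", index=False)
    paths["growth"] = out_dir / "growth.csv"
    pd.DataFrame({"day": list(NC_VALUES), "nc": list(NC_VALUES.values())}).to_csv(
        out_dir / "nc.csv", index=False
    )
    paths["nc"] = out_dir / "nc.csv"
    published_nni_table().to_csv(out_dir / "expected_nni.csv", index=False)
    paths["expected_nni"] = out_dir / "expected_nni.csv"
    (out_dir / "preset23.txt").write_text("\n".join(preset_features("paper23")) + "\n")
    paths["preset23"] = out_dir / "preset23.txt"
    return paths
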