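"""Cohort-table I/O, run configuration, and the end-to-end pipeline.

The cohort interchange format is a headed CSV (schema version 1).
Required columns::

    subject, cycle, age_y, sex, body_weight_kg, administered_dose_MBq,
    serum_creatinine_mg_per_dL, albumin_g_per_L, bilirubin_umol_per_L

Optional columns (used when present): measured_late_edr_uSv_per_h,
elapsed_h, luttotal, octtotal, and the derived ccr_ml_min / albi /
dose_per_bw.  Unknown columns are preserved on read and write.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clinical, prediction, quant, synthetic

logger = logging.getLogger("lutedr")

COHORT_SCHEMA_VERSION = 1

REQUIRED_COLUMNS = (
    "subject", "cycle", "age_y", "sex", "body_weight_kg",
    "administered_dose_MBq", "serum_creatinine_mg_per_dL",
    "albumin_g_per_L", "bilirubin_umol_per_L",
)
OPTIONAL_NUMERIC_COLUMNS = (
    "measured_late_edr_uSv_per_h", "elapsed_h", "luttotal", "octtotal",
    "ccr_ml_min", "albi", "dose_per_bw",
)
_NUMERIC_REQUIRED = tuple(
    c for c in REQUIRED_COLUMNS if c not in ("subject", "sex")
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _coerce_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"column {col!r}: non-numeric value {df[col].iloc[row]!r} "
            f"at row {row}"
        )
    return coerced


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema.

    Missing required columns raise, naming the column; non-numeric cells
    in numeric columns raise with the row index.  Unknown columns are
    kept as-is.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing column(s): {', '.join(missing)}")
    for col in _NUMERIC_REQUIRED:
        df[col] = _coerce_numeric(df, col)
    for col in OPTIONAL_NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = _coerce_numeric(df, col)
    df["cycle"] = df["cycle"].astype(int)
    df["subject"] = df["subject"].astype(str)
    df["sex"] = df["sex"].astype(str)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (full float precision, so read(write(x)) == x)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {', '.join(missing)}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_STAGES = ("simulate", "quantify", "fit", "predict", "evaluate")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``threshold_k`` is the multiplier in the ``mean + k*SD`` background
    threshold (default 2, the published rule); ``release_limit`` is the
    isolation-release bound in uSv/h.
    """

    output_dir: str = "lutedr_run"
    stages: tuple[str, ...] = DEFAULT_STAGES
    cohort_csv: str | None = None       # if set, 'simulate' is skipped for the cohort
    volume_path: str | None = None      # SUV volume (NIfTI) for 'quantify'
    muscle_mask_path: str | None = None
    body_mask_path: str | None = None
    max_sphere_diameter_mm: float = quant.MAX_SPHERE_DIAMETER_MM
    threshold_k: float = 2.0
    response_column: str = "measured_late_edr_uSv_per_h"
    predictor_columns: tuple[str, ...] = ("luttotal", "dose_per_bw")
    fixed_dose_MBq: float = prediction.DEFAULT_FIXED_DOSE_MBQ
    release_limit: float = prediction.RELEASE_LIMIT_USV_PER_H
    n_subjects: int = 111
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.threshold_k < 0:
            raise ValueError("threshold multiplier must be >= 0")
        if self.release_limit <= 0:
            raise ValueError("release limit must be positive")
        if self.fixed_dose_MBq <= 0:
            raise ValueError("fixed dose must be positive")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {', '.join(sorted(unknown))}")
        for name in ("cohort_csv", "volume_path", "muscle_mask_path",
                     "body_mask_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")
        if "simulate" not in self.stages:
            if "quantify" in self.stages and self.volume_path is None:
                raise ValueError("'quantify' without 'simulate' needs volume_path")
            if any(s in self.stages for s in ("fit", "predict", "evaluate")) \
                    and self.cohort_csv is None:
                raise ValueError("'fit'/'predict'/'evaluate' without 'simulate' "
                                 "need cohort_csv")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    if isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    if isinstance(cfg.predictor_columns, list):
        cfg.predictor_columns = tuple(cfg.predictor_columns)
    return cfg


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    Stages: simulate (phantom + cohort) -> quantify (threshold-based
    total uptake on the phantom) -> fit (dose-rate model + cross-tracer
    bridge, composed at the fixed dose) -> predict (pretreatment
    predictions with release flags) -> evaluate (RMSE/MAE and
    Bland-Altman).  All randomness flows from ``config.seed``; the
    manifest contains no timestamps, so identical configs produce
    identical manifests.
    """
    config.validate()
    configure_logging(config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "lutedr", "version": __version__},
        "config": _config_dict(config),
        "stages_run": [],
        "outputs": {},
    }
    state: dict = {}

    def _run(stage, fn):
        if stage not in config.stages:
            return
        logger.info("stage %s: start", stage)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            manifest["failed_stage"] = stage
            _write_json(out / "manifest.json", manifest)
            raise PipelineError(stage, exc) from exc
        manifest["stages_run"].append(stage)
        logger.info("stage %s: done", stage)

    def simulate():
        pspec = synthetic.PhantomSpec(seed=config.seed)
        vol, bg_mask, body_mask, truth = synthetic.generate_phantom(pspec)
        quant.write_volume(vol, out / "phantom_suv.nii.gz")
        quant.write_mask(bg_mask, vol.voxel_spacing_mm, out / "phantom_background_mask.nii.gz")
        quant.write_mask(body_mask, vol.voxel_spacing_mm, out / "phantom_body_mask.nii.gz")
        _write_json(out / "phantom_truth.json", {
            "compartments": list(truth.compartment_names),
            "volumes_mL": list(truth.volumes_mL),
            "uptakes": list(truth.uptakes),
            "total_uptake": truth.total_uptake,
            "background_suv_mean": truth.background_suv_mean,
            "background_suv_sd": truth.background_suv_sd,
        })
        cspec = synthetic.CohortSpec(n_subjects=config.n_subjects,
                                     seed=config.seed)
        cohort, ctruth = synthetic.generate_cohort(cspec)
        write_cohort(cohort, out / "cohort.csv")
        _write_json(out / "cohort_truth.json", ctruth.to_dict())
        state["volume"], state["muscle_mask"] = vol, bg_mask
        state["body_mask"], state["cohort"] = body_mask, cohort
        manifest["outputs"]["cohort"] = "cohort.csv"
        manifest["outputs"]["phantom"] = "phantom_suv.nii.gz"

    def quantify():
        if "volume" not in state:
            vol = quant.read_volume(config.volume_path, units="SUV")
            muscle = quant.read_mask(config.muscle_mask_path)
            body = (quant.read_mask(config.body_mask_path)
                    if config.body_mask_path else None)
        else:
            vol, muscle, body = (state["volume"], state["muscle_mask"],
                                 state["body_mask"])
        metrics, stats, sphere, _ = quant.quantify_volume(
            vol, muscle, body_mask=body, k=config.threshold_k,
            max_sphere_diameter_mm=config.max_sphere_diameter_mm)
        row = quant.metrics_row("phantom", "LUT", metrics, stats)
        row["sphere_radius_mm"] = sphere.radius_mm
        pd.DataFrame([row]).to_csv(out / "uptake_metrics.csv", index=False)
        state["metrics"] = metrics
        manifest["outputs"]["uptake_metrics"] = "uptake_metrics.csv"

    def _cohort() -> pd.DataFrame:
        if "cohort" not in state:
            df = read_cohort(config.cohort_csv)
            if "dose_per_bw" not in df.columns:
                df = clinical.add_derived_columns(df)
            state["cohort"] = df
        return state["cohort"]

    def fit():
        cohort = _cohort()
        edr_fit = prediction.fit_edr_model(
            cohort, response=config.response_column,
            uptake_col=config.predictor_columns[0],
            dose_col=config.predictor_columns[1])
        pairs = cohort[["luttotal", "octtotal"]].dropna()
        bridge = prediction.fit_uptake_bridge(pairs["luttotal"],
                                              pairs["octtotal"])
        predictor = prediction.compose(edr_fit, bridge,
                                       fixed_dose_MBq=config.fixed_dose_MBq)
        predictor.to_json(out / "model.json")
        edr_fit.ols.report().to_csv(out / "regression_report.csv", index=False)
        state["predictor"], state["edr_fit"] = predictor, edr_fit
        manifest["outputs"]["model"] = "model.json"
        manifest["outputs"]["regression_report"] = "regression_report.csv"

    def predict():
        cohort = _cohort()
        predictor = state["predictor"]
        pred = predictor.predict(cohort["octtotal"], cohort["body_weight_kg"])
        res = cohort[["subject", "cycle", "body_weight_kg", "octtotal"]].copy()
        res["predicted_late_edr_uSv_per_h"] = pred
        res["releasable"] = [
            prediction.classify_release(max(p, 0.0), limit=config.release_limit)
            for p in pred
        ]
        res.to_csv(out / "predictions.csv", index=False)
        state["predictions"] = res
        manifest["outputs"]["predictions"] = "predictions.csv"

    def evaluate():
        cohort = _cohort()
        pred = state["predictions"]["predicted_late_edr_uSv_per_h"]
        ev = prediction.evaluate(cohort[config.response_column], pred)
        ba = prediction.bland_altman(cohort["luttotal"], cohort["octtotal"])
        _write_json(out / "metrics.json", {
            "n": ev.n, "rmse_uSv_per_h": ev.rmse, "mae_uSv_per_h": ev.mae,
            "bland_altman_lut_vs_oct": {
                "bias": ba.bias, "sd": ba.sd,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": ba.n,
            },
        })
        manifest["outputs"]["metrics"] = "metrics.json"

    _run("simulate", simulate)
    _run("quantify", quantify)
    _run("fit", fit)
    _run("predict", predict)
    _run("evaluate", evaluate)
    _write_json(out / "manifest.json", manifest)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(d["stages"])
    d["predictor_columns"] = list(d["predictor_columns"])
    return d


def _write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
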