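"""Readers, writers, run configuration and the end-to-end pipeline.

Cohorts travel as a plain CSV plus a YAML sidecar holding the variable
metadata (kinds, distribution parameters, seed). FiND items are written
in the survey coding (1 = yes, 2 = no) and recoded to 1/0 on read.
Trained models are serialized to a single self-describing JSON file
(weights, grid, training parameters, standardization constants and
variable names), so an epidemiologist can inspect every number with a
text editor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .bootstrap import make_split_plan, run_bootstrap, statistics_table
from .cohort import CohortTable, ConfigurationError, VariableSpec, generate_cohort
from .pca import pca, score_plot_data
from .preprocessing import ZScoreScaler, standardize
from .scoring import (
    CLASS_NAMES,
    FIND_ITEM_NAMES,
    MFFP_ITEM_NAMES,
    cohort_labels,
    score_cohort,
)
from .som import SupervisedSOM
from .somdi import compute_somdi_table

logger = logging.getLogger("frailsom")


# -- cohort CSV + metadata sidecar ----------------------------------------


def write_cohort_csv(cohort: CohortTable, csv_path, meta_path) -> None:
    """Write a cohort as CSV plus a YAML metadata sidecar.

    FiND item columns are emitted in the 1=yes/2=no survey coding.
    """
    frame = pd.DataFrame({"patient_id": np.arange(cohort.n)})
    frame["true_class"] = cohort.true_class
    for name in cohort.variable_names:
        frame[name] = cohort.data[name].to_numpy()
    for name in MFFP_ITEM_NAMES:
        frame[name] = cohort.mffp_items[name].to_numpy()
    for name in FIND_ITEM_NAMES:
        # internal yes=1/no=0 -> survey yes=1/no=2
        frame[name] = np.where(cohort.mfind_items[name].to_numpy() == 1, 1, 2)
    frame.to_csv(csv_path, index=False)

    meta = {
        "seed": cohort.seed,
        "class_weights": [float(w) for w in cohort.class_weights],
        "find_item_coding": "survey12",
        "variables": [
            {
                "name": s.name,
                "kind": s.kind,
                "baseline": {
                    k: (list(map(float, v)) if isinstance(v, (list, tuple, np.ndarray)) else float(v))
                    for k, v in s.baseline.items()
                },
                "class_effects": [float(e) for e in s.class_effects],
            }
            for s in cohort.specs
        ],
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_cohort_csv(csv_path, meta_path) -> CohortTable:
    """Read a cohort CSV with its metadata sidecar back into memory."""
    meta = yaml.safe_load(Path(meta_path).read_text())
    frame = pd.read_csv(csv_path)
    specs = [
        VariableSpec(
            name=v["name"],
            kind=v["kind"],
            baseline=v["baseline"],
            class_effects=tuple(v.get("class_effects", (0.0, 0.0, 0.0))),
        )
        for v in meta["variables"]
    ]
    needed = (
        [s.name for s in specs] + list(MFFP_ITEM_NAMES) + list(FIND_ITEM_NAMES) + ["true_class"]
    )
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing column(s): {missing}")
    mfind = frame[list(FIND_ITEM_NAMES)].to_numpy()
    if meta.get("find_item_coding", "survey12") == "survey12":
        if mfind.size and not np.isin(mfind, (1, 2)).all():
            raise ValueError("FiND item columns must use the 1=yes/2=no survey coding")
        mfind = np.where(mfind == 1, 1, 0)
    return CohortTable(
        data=frame[[s.name for s in specs]].astype(float),
        specs=specs,
        true_class=frame["true_class"].to_numpy(dtype=int),
        mffp_items=frame[list(MFFP_ITEM_NAMES)].astype(int),
        mfind_items=pd.DataFrame(mfind, columns=list(FIND_ITEM_NAMES)),
        seed=meta.get("seed"),
        class_weights=tuple(meta.get("class_weights", (np.nan,) * 3)),
    )


def write_labels_csv(cohort: CohortTable, instrument: str, path) -> None:
    """Per-patient scores, class labels and (mFiND) categories as CSV."""
    assessments = score_cohort(cohort, instrument)
    pd.DataFrame(
        {
            "patient_id": np.arange(cohort.n),
            "score": [a.score for a in assessments],
            "class_label": [a.class_label for a in assessments],
            "find_category": [a.find_category or "" for a in assessments],
        }
    ).to_csv(path, index=False)


# -- model serialization ---------------------------------------------------


def save_model(som: SupervisedSOM, scaler: ZScoreScaler, variable_names, path) -> None:
    """Serialize a trained model (plus its scaler) to self-describing JSON."""
    payload = {
        "format": "frailsom-som/1",
        "grid": {"rows": som.grid_.rows, "cols": som.grid_.cols, "layout": som.grid_.layout},
        "params": som.get_params(),
        "classes": np.asarray(som.classes_).tolist(),
        "variable_names": list(variable_names),
        "w_features": som.w_features_.tolist(),
        "w_classes": som.w_classes_.tolist(),
        "scaler": {"mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Inverse of :func:`save_model`; returns (som, scaler, variable_names)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "frailsom-som/1":
        raise ValueError(f"{path} is not a frailsom model file")
    som = SupervisedSOM(**payload["params"])
    from .hexgrid import HexGrid

    som.grid_ = HexGrid(payload["grid"]["rows"], payload["grid"]["cols"])
    som.classes_ = np.asarray(payload["classes"])
    som.w_features_ = np.asarray(payload["w_features"], dtype=float)
    som.w_classes_ = np.asarray(payload["w_classes"], dtype=float)
    som.n_features_in_ = som.w_features_.shape[1]
    scaler = ZScoreScaler()
    scaler.mean_ = np.asarray(payload["scaler"]["mean"], dtype=float)
    scaler.scale_ = np.asarray(payload["scaler"]["scale"], dtype=float)
    scaler.n_features_in_ = scaler.mean_.shape[0]
    return som, scaler, payload["variable_names"]


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    n: int = 251
    seed: int = 0
    instrument: str = "mffp"
    grid_rows: int = 8
    grid_cols: int = 8
    epochs: int = 100
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: Optional[float] = None
    radius_final: float = 0.5
    class_weight: float = 3.0
    som_seed: int = 0
    iterations: int = 50
    bootstrap_seed: int = 0
    with_replacement: bool = False
    contrast: str = "mean"
    pca_components: int = 2

    def __post_init__(self):
        if self.n < 3:
            raise ConfigurationError("n must be >= 3")
        if self.instrument not in ("mffp", "mfind"):
            raise ConfigurationError(f"unknown instrument {self.instrument!r}")
        if self.contrast not in ("mean", "max"):
            raise ConfigurationError(f"unknown contrast {self.contrast!r}")
        if min(self.grid_rows, self.grid_cols) < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if self.epochs < 1 or self.iterations < 1:
            raise ConfigurationError("epochs and iterations must be >= 1")
        for name in ("lr_initial", "lr_final", "radius_final", "class_weight"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def som_params(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "epochs": self.epochs,
            "lr_initial": self.lr_initial,
            "lr_final": self.lr_final,
            "radius_initial": self.radius_initial,
            "radius_final": self.radius_final,
            "class_weight": self.class_weight,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# -- end-to-end pipeline ---------------------------------------------------


def run_pipeline(config: RunConfig, out_dir, cohort: Optional[CohortTable] = None) -> Path:
    """simulate-or-load → score → explore → train → validate → rank → render.

    Writes cohort.csv(+.meta.yaml), labels.csv, pca_scores.csv,
    pca_plot.png, model.som, stats.csv, somdi.csv, planes/ and run.log
    into ``out_dir``. Deterministic: rerunning with the same config gives
    byte-identical numeric outputs.
    """
    from .plots import render_hex_planes, render_pca_scores

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: list[tuple[str, float]] = []

    def stage(name):
        logger.info("stage %s", name)
        timings.append((name, time.perf_counter()))

    try:
        logger.info("config digest %s: %s", config.digest(), dataclasses.asdict(config))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage("simulate")
            if cohort is None:
                cohort = generate_cohort(config.n, seed=config.seed)
            write_cohort_csv(cohort, out / "cohort.csv", out / "cohort.meta.yaml")

            stage("score")
            labels = cohort_labels(cohort, config.instrument)
            write_labels_csv(cohort, config.instrument, out / "labels.csv")

            stage("explore")
            sm = standardize(cohort.values, cohort.variable_names)
            pca_res = pca(sm.Z, config.pca_components)
            pd.DataFrame(
                pca_res.scores,
                columns=[f"PC{j + 1}" for j in range(pca_res.scores.shape[1])],
            ).assign(class_label=labels).to_csv(out / "pca_scores.csv", index=False)
            render_pca_scores(score_plot_data(pca_res, labels), out / "pca_plot.png",
                              pca_res.explained_variance_fraction)

            stage("train")
            scaler = ZScoreScaler().fit(cohort.values)
            som = SupervisedSOM(random_state=config.som_seed, **config.som_params())
            som.fit(scaler.transform(cohort.values), labels)
            save_model(som, scaler, cohort.variable_names, out / "model.som")

            stage("validate")
            plan = make_split_plan(
                cohort.n, config.iterations, config.bootstrap_seed,
                with_replacement=config.with_replacement,
            )
            result = run_bootstrap(cohort.values, labels, plan, config.som_params())
            stats = statistics_table({config.instrument: result})
            stats.to_csv(out / "stats.csv")

            stage("rank")
            table = compute_somdi_table(som, cohort.variable_names, config.contrast)
            table.to_frame().to_csv(out / "somdi.csv", index=False)

            stage("render")
            render_hex_planes(som, out / "planes", cohort.variable_names)

        for w in caught:
            logger.warning("collected warning: %s", w.message)
        for (name, t0), (_, t1) in zip(timings, timings[1:] + [("end", time.perf_counter())]):
            logger.info("stage %s took %.2fs", name, t1 - t0)
        logger.info("pipeline complete: %s", out)
    except Exception:
        failed = timings[-1][0] if timings else "setup"
        logger.exception("pipeline failed in stage %s", failed)
        (out / "FAILED").write_text(f"stage: {failed}\n")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
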