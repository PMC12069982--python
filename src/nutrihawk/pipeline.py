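"""End-to-end pipeline: simulate/load -> normalize -> cluster -> split -> boost -> evaluate.

The stages mirror the hybrid method's workflow: min-max normalization of
the child-level features, FHO-k-means clustering whose cluster id is
appended to the feature block (one-hot), a stratified train/test split,
EGBF training and a per-class metrics report. A single global seed
deterministically derives every stage seed by hashing the stage name, so
adding a stage never perturbs earlier ones and any stage can be replayed
in isolation from the report's seed ledger.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .clustering import ClusteringModel, cluster as fit_cluster, select_k
from .egbf import EGBFConfig, EGBFModel, fit as fit_egbf
from .fho import FHOConfig
from .metrics import MetricsReport, macro_report
from .preprocess import NormalizationParams, apply_minmax, fit_minmax, split_train_test
from .synthetic import CohortSpec

__all__ = [
    "PipelineConfig", "PipelineReport", "run_pipeline",
    "save_bundle", "load_bundle", "stage_seed", "featurize_cohort",
]

BUNDLE_VERSION = 1

#: numeric encoding of the child-level schema (label column excluded)
FEATURE_COLUMNS = (
    "age_months", "sex", "height_cm", "weight_kg", "muac_cm",
    "residence", "income_index", "z_wfh", "z_hfa", "z_wfa",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of "<global_seed>:<stage>", below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything one run needs; see field comments for semantics."""

    seed: int = 0
    input_csv: str | None = None          # child-level CSV; None -> simulate
    n_records: int = 2000
    noise_sd: float = 0.3
    class_mixture: dict[str, float] | None = None
    normalize: bool = True
    n_clusters: int | None = 4            # fixed K; None -> use k_range
    k_range: list[int] | None = None      # silhouette-based selection
    fho: dict = field(default_factory=lambda: {"pop_size": 30, "max_iters": 60})
    test_fraction: float = 0.3
    egbf: dict = field(default_factory=dict)
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown pipeline config keys: {sorted(extra)}")
        return cls(**d)


@dataclass
class PipelineReport:
    seed: int
    seed_ledger: dict[str, int]
    chosen_k: int
    cluster_sizes: list[int]
    metrics: MetricsReport
    timings: dict[str, float]
    artifacts: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "seed_ledger": self.seed_ledger,
            "chosen_k": self.chosen_k,
            "cluster_sizes": self.cluster_sizes,
            "metrics": self.metrics.to_dict(),
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
            "artifacts": self.artifacts,
        }


def featurize_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric feature matrix plus label vector from a child-level table."""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    X = df.loc[:, list(FEATURE_COLUMNS)].copy()
    X["sex"] = (df["sex"] == "male").astype(float)
    X["residence"] = (df["residence"] == "urban").astype(float)
    y = df["label"].to_numpy() if "label" in df.columns else np.empty(0)
    return X.astype(float), y


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow; returns the report (and writes artifacts
    under ``config.out_dir`` when set)."""
    ledger = {s: stage_seed(config.seed, s)
              for s in ("simulate", "cluster", "split", "train")}
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if config.input_csv:
        cohort = pd.read_csv(config.input_csv)
    else:
        mixture = config.class_mixture or {
            lab: 1.0 / len(synthetic.LABELS) for lab in synthetic.LABELS}
        cohort = synthetic.generate_child_cohort(CohortSpec(
            n_records=config.n_records, class_mixture=mixture,
            noise_sd=config.noise_sd, seed=ledger["simulate"]))
    timings["load"] = time.perf_counter() - t0
    if out:
        cohort.to_csv(out / "cohort.csv", index=False)
        artifacts["cohort"] = str(out / "cohort.csv")

    X, y = featurize_cohort(cohort)
    if y.size == 0:
        raise ValueError("input table has no label column; cannot train")

    t0 = time.perf_counter()
    norm: NormalizationParams | None = None
    Xn = X
    if config.normalize:
        norm = fit_minmax(X)
        Xn = apply_minmax(X, norm)
    timings["normalize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fho_cfg = FHOConfig(seed=ledger["cluster"], **config.fho)
    if config.n_clusters is not None:
        cm = fit_cluster(Xn.to_numpy(), config.n_clusters, fho_cfg)
        chosen_k = config.n_clusters
    else:
        if not config.k_range:
            raise ValueError("set either n_clusters or k_range")
        report = select_k(Xn.to_numpy(), config.k_range, fho_cfg)
        chosen_k = report.chosen_k
        cm = report.models[chosen_k]
    timings["cluster"] = time.perf_counter() - t0

    onehot = pd.DataFrame(
        (cm.assignments[:, None] == np.arange(chosen_k)[None, :]).astype(float),
        columns=[f"cluster_{k}" for k in range(chosen_k)], index=Xn.index)
    Xc = pd.concat([Xn, onehot], axis=1)
    if out:
        clustered = cohort.copy()
        clustered["cluster"] = cm.assignments
        clustered.to_csv(out / "clustered.csv", index=False)
        artifacts["clustered"] = str(out / "clustered.csv")

    t0 = time.perf_counter()
    train_idx, test_idx = split_train_test(
        len(Xc), config.test_fraction, ledger["split"], labels=y)
    timings["split"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    egbf_cfg = EGBFConfig(seed=ledger["train"], **config.egbf)
    model = fit_egbf(Xc.to_numpy()[train_idx], y[train_idx], egbf_cfg)
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    y_pred = model.predict(Xc.to_numpy()[test_idx])
    proba = model.predict_proba(Xc.to_numpy()[test_idx])
    metrics = macro_report(y[test_idx], y_pred, proba, model.class_labels)
    timings["evaluate"] = time.perf_counter() - t0

    if out:
        save_bundle(out / "model.json", model, norm, cm)
        artifacts["model"] = str(out / "model.json")
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2, sort_keys=True)
        artifacts["metrics"] = str(out / "metrics.json")

    sizes = np.bincount(cm.assignments, minlength=chosen_k).tolist()
    report = PipelineReport(config.seed, ledger, chosen_k, sizes,
                            metrics, timings, artifacts)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        artifacts["report"] = str(out / "report.json")
    return report


def save_bundle(path, model: EGBFModel, norm: NormalizationParams | None,
                clustering: ClusteringModel | None) -> None:
    """Persist the trained model with its preprocessing state as one JSON."""
    doc = {
        "format_version": BUNDLE_VERSION,
        "egbf": model.to_dict(),
        "normalization": norm.to_dict() if norm else None,
        "clustering": clustering.to_dict() if clustering else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_bundle(path):
    """Inverse of save_bundle; checks the format version."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no model bundle at {p}")
    with open(p) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != BUNDLE_VERSION:
        raise ValueError(
            f"model bundle version {doc.get('format_version')} "
            f"not supported (expected {BUNDLE_VERSION})")
    model = EGBFModel.from_dict(doc["egbf"])
    norm = NormalizationParams.from_dict(doc["normalization"]) if doc["normalization"] else None
    cm = ClusteringModel.from_dict(doc["clustering"]) if doc["clustering"] else None
    return model, norm, cm
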