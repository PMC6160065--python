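"""End-to-end orchestration: QC -> features -> split -> models -> metrics.

The same engine serves three entry points: the ``woundspec`` CLI (disk
images + metadata CSV), the numbered analysis drivers (in-memory synthetic
cohorts), and the acceptance script. All outputs are plain text (CSV/JSON),
written atomically so interrupted runs never leave corrupt files.
"""
from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import images as img
from . import models as mdl
from . import stats as st
from .simulate import SyntheticCohort

__all__ = [
    "RunConfig",
    "atomic_write_text",
    "write_json",
    "write_csv",
    "channel_stats_from_cohort",
    "channel_stats_from_disk",
    "features_from_channel_stats",
    "analyze_channel_stats",
    "run_analysis",
    "simulate_to_dir",
]


@dataclass
class RunConfig:
    """Configuration of one analysis run (flat YAML key: value file)."""

    metadata_csv: str = ""
    image_root: str = ""
    output_dir: str = "results"
    # QC thresholds
    glare_max: float = 0.05
    blur_min: float = 1e-4
    blood_channel_margin: float = 0.25
    blood_max: float = 0.50
    # normalization / split
    normalize_scope: str = "train"  # train | all
    train_fraction: float = 0.75
    split_seed: int = 0
    # models
    model: str = "hca"  # hca | threshold_only
    n_components: object = "auto"
    cv_folds: int = 10
    decision_threshold: float = 0.5
    route_by: str = "truth"
    threshold_cutoff: float = 1.00
    # permutation test
    n_perm: int = 200
    perm_seed: int = 0
    perm_cv: int = 5
    perm_components: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.normalize_scope not in ("train", "all"):
            raise ValueError("normalize_scope must be 'train' or 'all'")
        if self.model not in ("hca", "threshold_only"):
            raise ValueError("model must be 'hca' or 'threshold_only'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def qc_thresholds(self) -> img.QCThresholds:
        return img.QCThresholds(
            glare_max=self.glare_max,
            blur_min=self.blur_min,
            blood_channel_margin=self.blood_channel_margin,
            blood_max=self.blood_max,
        )


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_csv(path, df: pd.DataFrame) -> None:
    atomic_write_text(path, df.to_csv(index=False))


METADATA_COLUMNS = [
    "image_id", "path", "roi_path", "patient_id", "wound_id",
    "debridement_index", "hospital", "wound_area_cm2", "days_post_injury",
    "age", "outcome",
]

_STATS_COLUMNS = [
    "image_id", "patient_id", "wound_id", "debridement_index", "hospital",
    "wound_area_cm2", "days_post_injury", "age", "outcome",
    "r_mean", "g_mean", "b_mean", "r_sem", "g_sem", "b_sem", "n_roi_pixels",
    "qc_pass", "qc_reasons", "glare_fraction", "blur_score", "blood_fraction",
]


def _stats_row(record: img.ImageRecord, image: img.RGBImage, rois,
               thresholds: img.QCThresholds) -> dict:
    union = img.ROIMask(np.logical_or.reduce([r.mask for r in rois]))
    qc = img.qc_screen(image, union, thresholds)
    ch = img.roi_channel_means(image, rois)
    row = {k: getattr(record, k) for k in (
        "image_id", "patient_id", "wound_id", "debridement_index", "hospital",
        "wound_area_cm2", "days_post_injury", "age", "outcome")}
    row.update(
        r_mean=ch.mean[0], g_mean=ch.mean[1], b_mean=ch.mean[2],
        r_sem=ch.sem[0], g_sem=ch.sem[1], b_sem=ch.sem[2],
        n_roi_pixels=ch.n_pixels,
        qc_pass=qc.passed, qc_reasons=";".join(qc.reasons),
        glare_fraction=qc.glare_fraction, blur_score=qc.blur_score,
        blood_fraction=qc.blood_fraction,
    )
    return row


def channel_stats_from_cohort(cohort: SyntheticCohort,
                              thresholds: img.QCThresholds | None = None) -> pd.DataFrame:
    """Per-image ROI channel statistics + QC for an in-memory cohort."""
    thr = thresholds or img.QCThresholds()
    rows = [_stats_row(o.record, o.image, [o.roi], thr) for o in cohort.observations]
    df = pd.DataFrame(rows, columns=_STATS_COLUMNS)
    df["true_sto2"] = [o.true_sto2 for o in cohort.observations]
    df["artifact"] = [o.artifact for o in cohort.observations]
    return df


def channel_stats_from_disk(metadata_csv, image_root="",
                            thresholds: img.QCThresholds | None = None) -> pd.DataFrame:
    """Load images and ROIs listed in a metadata CSV and compute stats + QC."""
    meta = pd.read_csv(metadata_csv)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata CSV is missing columns: {missing}")
    thr = thresholds or img.QCThresholds()
    root = Path(image_root) if image_root else Path(metadata_csv).parent
    rows = []
    for _, m in meta.iterrows():
        record = img.ImageRecord(
            image_id=str(m["image_id"]), patient_id=str(m["patient_id"]),
            wound_id=str(m["wound_id"]), debridement_index=int(m["debridement_index"]),
            hospital=str(m["hospital"]), wound_area_cm2=float(m["wound_area_cm2"]),
            days_post_injury=float(m["days_post_injury"]), age=float(m["age"]),
            outcome=str(m["outcome"]),
        )
        image = img.load_image(root / str(m["path"]))
        rois = img.load_roi_masks(root / str(m["roi_path"]),
                                  (image.height, image.width))
        rows.append(_stats_row(record, image, rois, thr))
    return pd.DataFrame(rows, columns=_STATS_COLUMNS)


def features_from_channel_stats(stats: pd.DataFrame,
                                ref: feat.NormalizationReference) -> pd.DataFrame:
    """The canonical feature table: hospital-normalized channels -> 7 raw
    indices -> 7 variable-normalized indices, plus clinical covariates."""
    rows = []
    for _, m in stats.iterrows():
        ch = feat.ChannelMeans(m["r_mean"], m["g_mean"], m["b_mean"])
        fv = feat.extract_features(m["hospital"], ch, ref)
        row = {
            "image_id": m["image_id"],
            "hospital": m["hospital"],
            "outcome": m["outcome"],
            **fv.raw,
            **fv.normalized,
            "wound_area_cm2": m["wound_area_cm2"],
            "days_post_injury": m["days_post_injury"],
            "age": m["age"],
        }
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["image_id", "hospital", "outcome", *feat.MODEL_PREDICTORS],
    )


def _metrics_payload(cm: st.ConfusionMatrix) -> dict:
    m = st.confusion_metrics(cm)
    dor, lo, hi = st.diagnostic_odds_ratio(cm)
    return {
        "confusion_matrix": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "accuracy": m.accuracy,
        "dor": dor,
        "dor_ci": [lo, hi],
    }


def analyze_channel_stats(stats: pd.DataFrame, cfg: RunConfig, log=None):
    """Run the full modeling stage on a channel-stats table.

    Returns (results dict, features DataFrame, group-comparison DataFrame,
    PCA scores DataFrame, fitted hierarchical model or None).
    """
    log = log or (lambda msg: None)
    n_total = len(stats)
    kept = stats[stats["qc_pass"].astype(bool)].reset_index(drop=True)
    n_disregarded = n_total - len(kept)
    log(f"quality screen: {n_disregarded} of {n_total} images disregarded")
    if kept.empty:
        raise ValueError("all images failed quality screening; nothing to analyze")

    # split first so the normalizer can be fit leakage-free on training rows
    train_idx, val_idx = mdl.stratified_indices(
        kept["outcome"].to_numpy(object), cfg.train_fraction, cfg.split_seed
    )
    fit_rows = kept.iloc[train_idx] if cfg.normalize_scope == "train" else kept
    ref = feat.fit_normalizer(
        (
            (m["hospital"], feat.ChannelMeans(m["r_mean"], m["g_mean"], m["b_mean"]))
            for _, m in fit_rows.iterrows()
        ),
        fit_population=f"{cfg.normalize_scope} (n={len(fit_rows)})",
    )
    features = features_from_channel_stats(kept, ref)

    comparison = st.group_comparison_table(
        features, [f"{n}_norm" for n in feat.RAW_INDEX_NAMES]
    )

    ds = mdl.LabeledDataset.from_frame(features, log=log)
    train = ds.subset(train_idx)
    val = ds.subset(val_idx)

    results: dict = {
        "n_images": n_total,
        "n_qc_disregarded": n_disregarded,
        "n_train": train.n,
        "n_validation": val.n,
        "split_seed": cfg.split_seed,
        "normalize_scope": cfg.normalize_scope,
    }

    # univariate threshold model on the normalized (R-B)/(R^2+B^2) index
    # (the variable has mean 1 on the fit population, so the default 1.00
    # cutoff splits wounds at the population average)
    thr_vals = features["rb_over_r2b2_norm"].to_numpy(float)
    thr_pred = mdl.threshold_classify(thr_vals, cutoff=cfg.threshold_cutoff)
    classified = thr_pred != "unclassified"
    results["threshold_model"] = {
        "cutoff": cfg.threshold_cutoff,
        "n_unclassified": int((~classified).sum()),
        **_metrics_payload(
            st.ConfusionMatrix.from_labels(ds.y2[classified], thr_pred[classified])
        ),
    }

    scores, _, evr = mdl.pca_fit(ds.X, k=2)
    pca_scores = pd.DataFrame(
        {"image_id": ds.ids, "outcome": ds.y3,
         "pc1": scores[:, 0], "pc2": scores[:, 1]}
    )
    results["pca_explained_variance"] = [float(v) for v in evr]

    model = None
    if cfg.model == "hca":
        model = mdl.fit_hierarchical(
            train, A=cfg.n_components, cv=cfg.cv_folds,
            seed=cfg.split_seed, threshold=cfg.decision_threshold,
            route_by=cfg.route_by,
        )
        val_pred = mdl.predict_hierarchical(model, val.X)
        cm = st.ConfusionMatrix.from_labels(val.y2, val_pred)
        results["hca"] = {
            "stage1_components": model.stage1.n_components,
            "stage2_components": model.stage2.n_components,
            **_metrics_payload(cm),
        }
        results.update(_metrics_payload(cm))

        perm = mdl.permutation_test(
            train.X, train.y3,
            mdl.hierarchical_recipe(A=cfg.perm_components,
                                    threshold=cfg.decision_threshold,
                                    route_by=cfg.route_by),
            n_perm=cfg.n_perm, cv=cfg.perm_cv, seed=cfg.perm_seed,
            score_transform=mdl.collapse_to_binary,
        )
        results["permutation_p"] = perm.p_insignificance
        results["permutation_observed_cv_accuracy"] = perm.observed
        results["perm_seed"] = cfg.perm_seed
        log(
            f"hierarchical model: validation accuracy "
            f"{results['accuracy']:.3f}, permutation p {perm.p_insignificance:.4f}"
        )
    return results, features, comparison, pca_scores, model


def run_analysis(cfg: RunConfig) -> dict:
    """Disk-to-disk pipeline: read metadata + images, write all reports.

    Outputs under ``cfg.output_dir``: features.csv, group_comparison.csv,
    pca_scores.csv, model.json (hca mode), metrics.json, normalizer.json and
    run.log. Returns the metrics dict.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stats = channel_stats_from_disk(cfg.metadata_csv, cfg.image_root,
                                    cfg.qc_thresholds())
    results, features, comparison, pca_scores, model = analyze_channel_stats(
        stats, cfg, log=log
    )
    write_csv(out / "features.csv", features)
    write_csv(out / "group_comparison.csv", comparison)
    write_csv(out / "pca_scores.csv", pca_scores)
    if model is not None:
        write_json(out / "model.json", model.to_json_dict())
    write_json(out / "metrics.json", results)
    atomic_write_text(out / "run.log", "\n".join(log_lines) + "\n")
    return results


def simulate_to_dir(cohort: SyntheticCohort, outdir) -> pd.DataFrame:
    """Write a synthetic cohort to disk in the pipeline's input layout:
    images/*.png, masks/*.png, cohort.csv (metadata schema + true_sto2) and
    a flat config echo."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    meta = cohort.metadata()
    meta.insert(1, "path", [f"images/{i}.png" for i in meta["image_id"]])
    meta.insert(2, "roi_path", [f"masks/{i}.png" for i in meta["image_id"]])
    for obs in cohort.observations:
        iid = obs.record.image_id
        img.save_image(obs.image, outdir / "images" / f"{iid}.png")
        mask_u8 = (obs.roi.mask.astype(np.uint8)) * 255
        from PIL import Image as _PILImage

        _PILImage.fromarray(mask_u8, mode="L").save(outdir / "masks" / f"{iid}.png")
    write_csv(outdir / "cohort.csv", meta)
    cfg = cohort.config
    echo_items = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "image_size": list(cfg.image_size),
        "noise_sd": cfg.noise_sd,
        "class_proportions": dict(cfg.class_proportions),
        "artifact_rates": dict(cfg.artifact_rates),
    }
    atomic_write_text(
        outdir / "config_echo.yaml",
        "\n".join(f"{k}: {v}" for k, v in echo_items.items()) + "\n",
    )
    return meta
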