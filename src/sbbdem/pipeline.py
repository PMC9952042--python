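"""End-to-end orchestration: simulate -> enhance -> score -> evaluate -> classify.

Everything is deterministic given the config (which includes the seed);
each report embeds the config hash so runs can be traced back to their
parameters.  JSON numbers are rounded to 10 decimals purely to keep
reports byte-stable across platforms.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import FEATURE_NAMES, KNNConfig, chi_square_filter, extract_features, knn_cv, pca_reduce, segment_in_box
from .config import RunConfig
from .enhance import FactorGrid, enhance_by_density
from .io import write_boxes, write_detections, write_image, write_mask, write_split_manifest
from .metrics import detection_rate, cs_accuracy, mask_eval, match_detections, mean_average_precision
from .phantom import Phantom, PhantomSpec, generate_cohort, simulate_detections
from .preprocess import split_train_test
from .quality import brisque_score, mean_intensity, mse
from .texture import glcm, texture_features

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_cohort", "classification_experiment"]


def _round(obj):
    if isinstance(obj, float):
        return round(obj, 10)
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    return obj


def _dump(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(_round(doc), indent=2, sort_keys=True) + "\n")


def simulate_cohort(cfg: RunConfig) -> list[Phantom]:
    base = PhantomSpec(
        width=cfg.phantom_size,
        height=cfg.phantom_size,
        n_masses=cfg.n_masses,
        mass_radius=cfg.mass_radius,
        mass_contrast=cfg.mass_contrast,
        noise_sigma=cfg.noise_sigma,
    )
    return generate_cohort(cfg.n_phantoms, cfg.density_mix, seed=cfg.seed, base_spec=base)


def classification_experiment(
    phantoms: list[Phantom],
    enhanced: dict[str, np.ndarray],
    cfg: RunConfig,
) -> dict:
    """Segment each mass in its ground-truth box, extract features, run CV."""
    rows, labels = [], []
    for ph in phantoms:
        img = enhanced.get(ph.image_id, ph.image)
        for box, label in zip(ph.boxes, ph.labels):
            try:
                seg = segment_in_box(img, box)
                feats = extract_features(img, seg, levels=cfg.glcm_levels)
            except ValueError as exc:
                logger.warning("skipping mass in %s: %s", ph.image_id, exc)
                continue
            rows.append(feats)
            labels.append(label)
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES)).fillna(0.0)
    y = np.asarray(labels)
    selected = list(table.columns)
    if cfg.feature_select == "chi2":
        selected = chi_square_filter(table, y, chi2_min=cfg.chi2_min)
        table = table[selected]
    elif cfg.feature_select == "pca":
        table, _, _ = pca_reduce(table, cfg.pca_components)
        selected = list(table.columns)
    class_counts = pd.Series(y).value_counts()
    if len(class_counts) < 2 or class_counts.min() < cfg.cv_folds:
        return {
            "n_masses": len(y),
            "skipped": "too few masses per class for cross-validation",
            "class_counts": class_counts.to_dict(),
        }
    report = knn_cv(table, y, KNNConfig(k=cfg.knn_k, folds=cfg.cv_folds), seed=cfg.seed)
    return {
        "n_masses": len(y),
        "features_used": selected,
        "fold_accuracy": list(report.fold_accuracy),
        "mean_accuracy": report.mean_accuracy,
        "auc": report.auc,
        "confusion": report.confusion.tolist(),
    }


def run_pipeline(cfg: RunConfig, out_dir: str | Path, save_images: bool = False) -> Path:
    """Execute every stage on a simulated cohort and persist the reports.

    Writes into ``out_dir``: split_manifest.json, enhancement_report.json,
    scores.csv, texture.csv, metrics.json, cv_report.json (and, when
    ``save_images``, the phantom/enhanced PNGs, masks and box CSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(), "version": __version__}

    phantoms = simulate_cohort(cfg)
    ids = [ph.image_id for ph in phantoms]
    by_id = {ph.image_id: ph for ph in phantoms}

    train, test = split_train_test(ids, cfg.train_fraction, seed=cfg.seed)
    write_split_manifest(out / "split_manifest.json", train, test, cfg.seed)

    # Stage 1: density-group-wise enhancement
    grid = FactorGrid(cfg.grid_lo, cfg.grid_hi, cfg.grid_step)
    scorer = (lambda img: brisque_score(img, backend=cfg.scorer))
    results = enhance_by_density(
        {i: by_id[i].image for i in ids},
        {i: by_id[i].acr_level for i in ids},
        grid=grid,
        scorer=scorer,
        masks={i: by_id[i].breast_mask for i in ids},
    )
    _dump(out / "enhancement_report.json", {
        **meta,
        "per_image": {
            i: {"factor": r.factor, "otsu_t": r.otsu_t, "lower_cap": r.lower_cap, "upper_cap": r.upper_cap}
            for i, r in results.items()
        },
        "score_tables": {
            i: {str(k): v for k, v in r.score_table.items()} for i, r in list(results.items())[:1]
        },
    })

    # Stage 1 evaluation: quality + texture before/after
    score_rows, texture_rows = [], []
    for i in ids:
        orig, enh = by_id[i].image, results[i].enhanced
        score_rows += [
            {"image_id": i, "metric": "mse", "value": mse(enh, orig)},
            {"image_id": i, "metric": "mean_intensity_original", "value": mean_intensity(orig)},
            {"image_id": i, "metric": "mean_intensity_enhanced", "value": mean_intensity(enh)},
        ]
        for tag, img in (("original", orig), ("enhanced", enh)):
            tf = texture_features(glcm(img, levels=cfg.glcm_levels, offset=cfg.glcm_offset))
            texture_rows.append({"image_id": i, "variant": tag, **tf.as_dict()})
    pd.DataFrame(score_rows).round(10).to_csv(out / "scores.csv", index=False)
    pd.DataFrame(texture_rows).round(10).to_csv(out / "texture.csv", index=False)

    # Stage 2 evaluation: simulated detector output scored against ground truth
    rng = np.random.default_rng(cfg.seed + 1)
    all_dets, per_image = [], []
    for ph in phantoms:
        dets = simulate_detections(ph, rng)
        all_dets.extend(dets)
        per_image.append(match_detections(dets, list(ph.boxes), cfg.iou_min, cfg.cs_min))
    write_detections(out / "detections.csv", all_dets)
    gts_with_masses = [ph for ph in phantoms if ph.boxes]
    metrics_doc = dict(meta)
    if gts_with_masses:
        metrics_doc.update(_pooled_map(phantoms, all_dets, cfg))
        metrics_doc["detection_rate_pct"] = detection_rate(per_image)
        try:
            metrics_doc["cs_accuracy_pct"] = cs_accuracy(per_image)
        except ValueError:
            metrics_doc["cs_accuracy_pct"] = None
        # Stage 3 segmentation quality inside ground-truth boxes
        seg_scores = []
        for ph in gts_with_masses:
            img = results[ph.image_id].enhanced
            for box, gt_mask in zip(ph.boxes, ph.mass_masks):
                try:
                    pred = segment_in_box(img, box)
                except ValueError:
                    continue
                seg_scores.append(mask_eval(pred, gt_mask))
        if seg_scores:
            metrics_doc["segmentation"] = {
                "mean_iou_mass": float(np.mean([s.iou_mass for s in seg_scores])),
                "mean_accuracy": float(np.mean([s.accuracy for s in seg_scores])),
                "n_masses": len(seg_scores),
            }
    _dump(out / "metrics.json", metrics_doc)

    # Stage 3: benign/malignant classification
    cv_doc = classification_experiment(phantoms, {i: results[i].enhanced for i in ids}, cfg)
    _dump(out / "cv_report.json", {**meta, **cv_doc})

    if save_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        box_rows = []
        for ph in phantoms:
            write_image(img_dir / f"{ph.image_id}.png", ph.image)
            write_image(img_dir / f"{ph.image_id}.enhanced.png", results[ph.image_id].enhanced)
            write_mask(img_dir / f"{ph.image_id}.breast.png", ph.breast_mask)
            write_mask(img_dir / f"{ph.image_id}.dense.png", ph.dense_mask)
            for k, (m, box, label) in enumerate(zip(ph.mass_masks, ph.boxes, ph.labels)):
                write_mask(img_dir / f"{ph.image_id}.mass{k}.png", m)
                box_rows.append({
                    "image_id": ph.image_id, "x": box.x, "y": box.y, "w": box.w, "h": box.h,
                    "label": label, "acr_level": ph.acr_level,
                })
        write_boxes(out / "boxes.csv", box_rows)
    return out


def _pooled_map(phantoms, all_dets, cfg: RunConfig) -> dict:
    """Single-class mAP over the whole cohort, with per-image GT bookkeeping.

    Boxes from different images must not match each other, so ground
    truths and detections are offset into disjoint coordinate slabs per
    image before pooling.
    """
    from .metrics import BoundingBox, Detection

    offset = 0
    step = max(ph.image.shape[1] for ph in phantoms) * 4
    pooled_dets, pooled_gts = [], []
    for ph in phantoms:
        for box in ph.boxes:
            pooled_gts.append(BoundingBox(box.x + offset, box.y, box.w, box.h))
        for d in (d for d in all_dets if d.image_id == ph.image_id):
            pooled_dets.append(Detection(BoundingBox(d.box.x + offset, d.box.y, d.box.w, d.box.h), d.cs))
        offset += step
    if not pooled_gts:
        return {}
    curve, ratio = mean_average_precision(pooled_dets, pooled_gts, cfg.iou_min, cfg.cs_min)
    return {
        "map_pr_auc": curve.ap,
        "precision_ratio": None if np.isnan(ratio) else ratio,
    }
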