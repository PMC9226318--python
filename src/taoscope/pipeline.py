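"""End-to-end orchestration: simulate -> detect -> crop -> segment ->
motility -> signs -> evaluate.

Stages communicate through files (PNG/CSV/JSON) so each one is
independently testable and replaceable by a learned component.  Per-image
failures are logged and skipped; a run fails only on structural errors.
``report.json`` is a pure function of the configuration and seed (no
timestamps, no absolute paths), so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage import transform as sk_transform

from . import __version__
from .annotation import EyeSegmentation, load_mask, save_mask
from .detection import BoundingBox, EyeCrop, EyeDetector, crop_and_resize, detection_accuracy
from .evaluation import (
    MetricRow,
    aggregate_mean_row,
    manifest_prevalences,
    metric_row,
    split_cohort,
    youden_threshold,
)
from .motility import diagnose_patient
from .segmentation import ThresholdEyeSegmenter
from .signs import SIGNS, build_registry
from .synthetic import (
    DEFAULT_PREVALENCES,
    DEFAULT_VIEW_PLAN,
    CohortManifest,
    gaze,
    simulate_cohort,
)

logger = logging.getLogger("taoscope")


@dataclass
class PipelineConfig:
    """Fully serializable run configuration.

    The effective config is echoed into the run directory; ``report.json``
    embeds it (paths excluded) so a report is traceable to its settings.
    """

    seed: int = 7
    n_patients: int = 50
    image_size: int = 160
    canvas_size: Tuple[int, int] = (320, 640)
    crop_size: int = 224
    noise_sigma: float = 5.0 / 255.0
    prevalences: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    view_plan: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_VIEW_PLAN))
    tolerance_px: Optional[float] = None          # None = auto: max(1, 0.02 r)
    split_fractions: Tuple[float, float, float] = (0.7, 0.1, 0.2)
    n_boot: int = 200
    use_ground_truth_masks: bool = False
    include_flagged_in_mean: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas_size"] = list(self.canvas_size)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "canvas_size" in d:
            d["canvas_size"] = tuple(d["canvas_size"])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, run_dir: Path) -> CohortManifest:
    cohort_dir = run_dir / "cohort"
    return simulate_cohort(
        config.n_patients, cohort_dir,
        prevalences=config.prevalences, view_plan=config.view_plan,
        seed=config.seed, image_size=config.image_size,
        canvas_size=config.canvas_size, noise_sigma=config.noise_sigma,
    )


def stage_detect(config: PipelineConfig, run_dir: Path, manifest: CohortManifest) -> pd.DataFrame:
    """Run the detector on every face image; write boxes.csv."""
    detector = EyeDetector()
    cohort = run_dir / "cohort"
    rows = []
    face_rows = manifest.images[manifest.images["view_type"] != "lateral"]
    for image_path, group in face_rows.groupby("image_path", sort=True):
        img = np.asarray(Image.open(cohort / image_path))
        boxes = detector.detect(img)
        if len(boxes) < 2:
            logger.warning("detect: %s: %d candidate(s), skipped", image_path, len(boxes))
            continue
        for box, side in zip(boxes, ("right", "left")):
            rows.append({"image_path": image_path, "eye_side": side,
                         "x0": box.x0, "y0": box.y0, "x1": box.x1, "y1": box.y1,
                         "score": box.score})
    df = pd.DataFrame(rows, columns=["image_path", "eye_side", "x0", "y0", "x1", "y1", "score"])
    df.to_csv(run_dir / "boxes.csv", index=False)
    return df


def _detection_result(manifest: CohortManifest, boxes: pd.DataFrame, iou_threshold=0.5):
    preds, gts = [], []
    face_rows = manifest.images[manifest.images["view_type"] != "lateral"]
    by_image = dict(tuple(boxes.groupby("image_path"))) if len(boxes) else {}
    for image_path, group in face_rows.groupby("image_path", sort=True):
        gts.append([BoundingBox(r.box_x0, r.box_y0, r.box_x1, r.box_y1)
                    for r in group.itertuples()])
        pred_group = by_image.get(image_path)
        preds.append([] if pred_group is None else
                     [BoundingBox(r.x0, r.y0, r.x1, r.y1, r.score) for r in pred_group.itertuples()])
    return detection_accuracy(preds, gts, iou_threshold)


def stage_crop(config: PipelineConfig, run_dir: Path, boxes: pd.DataFrame) -> pd.DataFrame:
    """Crop and resize detected eyes; write crops/*.png and crops.csv."""
    cohort = run_dir / "cohort"
    crops_dir = run_dir / "crops"
    crops_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for image_path, group in boxes.groupby("image_path", sort=True):
        img = np.asarray(Image.open(cohort / image_path))
        for r in group.itertuples():
            box = BoundingBox(r.x0, r.y0, r.x1, r.y1, r.score)
            crop = crop_and_resize(img, box, config.crop_size, eye_side=r.eye_side)
            name = f"{Path(image_path).stem}_{r.eye_side}.png"
            Image.fromarray((crop.image * 255).astype(np.uint8)).save(crops_dir / name)
            rows.append({"image_path": image_path, "eye_side": r.eye_side,
                         "crop_path": f"crops/{name}",
                         "x0": box.x0, "y0": box.y0, "x1": box.x1, "y1": box.y1})
    df = pd.DataFrame(rows, columns=["image_path", "eye_side", "crop_path",
                                     "x0", "y0", "x1", "y1"])
    df.to_csv(run_dir / "crops.csv", index=False)
    return df


def stage_segment(config: PipelineConfig, run_dir: Path, crops: pd.DataFrame) -> pd.DataFrame:
    """Segment every crop; write predicted masks (indexed PNG)."""
    segmenter = ThresholdEyeSegmenter()
    masks_dir = run_dir / "masks_pred"
    masks_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in crops.itertuples():
        img = np.asarray(Image.open(run_dir / r.crop_path)).astype(np.float32) / 255.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg = segmenter.segment(img)
        name = Path(r.crop_path).name
        save_mask(seg, masks_dir / name)
        rows.append({**r._asdict(), "mask_pred_path": f"masks_pred/{name}"})
    df = pd.DataFrame(rows).drop(columns=["Index"], errors="ignore")
    df.to_csv(run_dir / "segmented.csv", index=False)
    return df


def _crop_mask_to_native(seg: EyeSegmentation, box: BoundingBox) -> EyeSegmentation:
    """Undo the square resize: nearest-neighbour map back to box resolution,
    restoring the corneal circle's circularity for the geometry rules."""
    h = max(2, int(round(box.height)))
    w = max(2, int(round(box.width)))
    native = sk_transform.resize(seg.labels, (h, w), order=0, preserve_range=True,
                                 anti_aliasing=False).astype(np.uint8)
    return EyeSegmentation(native)


def stage_motility(config: PipelineConfig, run_dir: Path, manifest: CohortManifest,
                   segmented: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Per-patient motility diagnosis; write verdicts.csv and patients-level calls."""
    cohort = run_dir / "cohort"
    gaze_rows = manifest.images[
        (manifest.images["view_type"] == "nine_gaze") & (manifest.images["gaze"] != "primary")
    ]
    seg_lookup = {}
    if segmented is not None:
        seg_lookup = {(r.image_path, r.eye_side): r for r in segmented.itertuples()}
    verdict_rows = []
    patient_rows = []
    for pid, group in gaze_rows.groupby("patient_id", sort=True):
        exams = []
        for r in group.itertuples():
            g = gaze(r.gaze)
            if config.use_ground_truth_masks or segmented is None:
                seg = load_mask(cohort / r.mask_path)
            else:
                rec = seg_lookup.get((r.image_path, r.eye_side))
                if rec is None:
                    logger.warning("motility: no segmentation for %s/%s, skipped",
                                   r.image_path, r.eye_side)
                    continue
                seg224 = load_mask(run_dir / rec.mask_pred_path)
                seg = _crop_mask_to_native(seg224, BoundingBox(rec.x0, rec.y0, rec.x1, rec.y1))
            exams.append((r.eye_side, g, seg))
        if not exams:
            logger.warning("motility: patient %s has no assessable gaze, skipped", pid)
            continue
        try:
            report = diagnose_patient(exams, config.tolerance_px)
        except ValueError as exc:
            logger.warning("motility: patient %s: %s", pid, exc)
            continue
        for v in report.verdicts:
            verdict_rows.append({
                "patient_id": pid, "eye_side": v.eye_side, "gaze": v.gaze.name,
                "relation": v.relation.relation if v.relation else "indeterminate",
                "signed_clearance": (round(v.relation.signed_clearance, 4)
                                     if v.relation else ""),
                "rule_applied": v.rule_applied,
                "impaired": "" if v.impaired is None else int(v.impaired),
            })
        margin = report.impairment_margin
        patient_rows.append({
            "patient_id": pid,
            "patient_impaired": int(report.patient_impaired),
            "impairment_margin": round(margin, 4),
            "probability": round(1.0 / (1.0 + np.exp(-margin / 2.0)), 6),
            "n_indeterminate": report.n_indeterminate,
        })
    pd.DataFrame(verdict_rows).to_csv(run_dir / "verdicts.csv", index=False)
    df = pd.DataFrame(patient_rows)
    df.to_csv(run_dir / "motility_patients.csv", index=False)
    return df


def stage_signs(config: PipelineConfig, run_dir: Path, manifest: CohortManifest,
                segmented: Optional[pd.DataFrame], motility_patients: pd.DataFrame) -> pd.DataFrame:
    """Per-patient sign probabilities; write scores.csv.

    Feature signs are scored on anteroposterior-view crops (max over the
    two eyes); the eye-movement probability comes from the motility stage's
    margin.
    """
    registry = build_registry()
    cohort = run_dir / "cohort"
    ap_rows = manifest.images[manifest.images["view_type"] == "anteroposterior"]
    seg_lookup = {}
    if segmented is not None:
        seg_lookup = {(r.image_path, r.eye_side): r for r in segmented.itertuples()}
    feature_signs = [s for s in SIGNS if s != "eye_movement_disorders"]
    per_patient: Dict[str, Dict[str, float]] = {}
    for r in ap_rows.itertuples():
        if config.use_ground_truth_masks or segmented is None:
            seg = load_mask(cohort / r.mask_path)
            tile = np.asarray(Image.open(cohort / r.image_path)).astype(np.float32) / 255.0
            y, x, s = r.tile_y, r.tile_x, config.image_size
            crop = EyeCrop(tile[y:y + s, x:x + s], box=None, eye_side=r.eye_side)
        else:
            rec = seg_lookup.get((r.image_path, r.eye_side))
            if rec is None:
                logger.warning("signs: no segmentation for %s/%s, skipped",
                               r.image_path, r.eye_side)
                continue
            seg = load_mask(run_dir / rec.mask_pred_path)
            img = np.asarray(Image.open(run_dir / rec.crop_path)).astype(np.float32) / 255.0
            crop = EyeCrop(img, box=BoundingBox(rec.x0, rec.y0, rec.x1, rec.y1),
                           eye_side=r.eye_side)
        scores = per_patient.setdefault(r.patient_id, {})
        for sign in feature_signs:
            s = registry[sign].score_one(crop, seg)
            scores[sign] = max(scores.get(sign, 0.0), s.probability)
    margin_lookup = (dict(zip(motility_patients["patient_id"], motility_patients["probability"]))
                     if len(motility_patients) else {})
    rows = []
    for pid in sorted(set(manifest.patients["patient_id"])):
        scores = per_patient.get(pid, {})
        if pid in margin_lookup:
            scores["eye_movement_disorders"] = float(margin_lookup[pid])
        for sign in SIGNS:
            if sign in scores:
                rows.append({"patient_id": pid, "sign": sign,
                             "probability": round(scores[sign], 6),
                             "flagged": int(getattr(registry[sign], "flagged", False))})
    df = pd.DataFrame(rows, columns=["patient_id", "sign", "probability", "flagged"])
    df.to_csv(run_dir / "scores.csv", index=False)
    return df


def _row_dict(row: MetricRow) -> dict:
    def _r(x):
        return None if x is None else round(float(x), 6)
    return {
        "sign": row.sign, "auroc": _r(row.auroc),
        "auroc_ci": None if row.auroc_ci is None else [_r(row.auroc_ci[0]), _r(row.auroc_ci[1])],
        "sensitivity": _r(row.sensitivity),
        "sensitivity_ci": None if row.sensitivity_ci is None else [_r(row.sensitivity_ci[0]), _r(row.sensitivity_ci[1])],
        "specificity": _r(row.specificity),
        "specificity_ci": None if row.specificity_ci is None else [_r(row.specificity_ci[0]), _r(row.specificity_ci[1])],
        "f1": _r(row.f1), "flagged": bool(row.flagged),
    }


def stage_evaluate(config: PipelineConfig, run_dir: Path, manifest: CohortManifest,
                   scores: pd.DataFrame, detection) -> dict:
    """Patient-level split, thresholding, per-sign metrics and report.json."""
    labels = manifest.patients.set_index("patient_id")
    train, val, test = split_cohort(manifest, config.split_fractions, config.seed)
    wide = scores.pivot(index="patient_id", columns="sign", values="probability")
    rows = []
    for sign in SIGNS:
        flagged = bool(scores.loc[scores["sign"] == sign, "flagged"].max()) if len(scores) else False
        if sign not in wide.columns:
            rows.append(MetricRow(sign, flagged=flagged))
            continue

        def _subset(ids):
            sub = wide.reindex(ids)[sign].dropna()
            return sub.to_numpy(), labels.loc[sub.index, sign].to_numpy()

        s_val, y_val = _subset(val)
        s_test, y_test = _subset(test)
        # operating threshold frozen before test evaluation: Youden on the
        # validation split, widened to train+validation when the validation
        # split is single-class (small cohorts)
        try:
            thr = youden_threshold(s_val, y_val)
        except ValueError:
            try:
                s_tv, y_tv = _subset(train + val)
                thr = youden_threshold(s_tv, y_tv)
            except ValueError:
                thr = 0.5
        rows.append(metric_row(sign, s_test, y_test, thr, config.n_boot, config.seed,
                               flagged=flagged))
    try:
        mean_row = aggregate_mean_row(rows, include_flagged=config.include_flagged_in_mean)
    except ValueError:
        mean_row = MetricRow("mean")
    prevalence = manifest_prevalences(manifest)
    report = {
        "tool": {"name": "taoscope", "version": __version__},
        "config": config.to_dict(),
        "cohort": {"n_patients": int(len(manifest.patients)),
                   "n_images": int(manifest.images["image_path"].nunique())},
        "split": {"n_train": len(train), "n_validation": len(val), "n_test": len(test)},
        "detection": None if detection is None else {
            "accuracy": round(detection.accuracy, 6),
            "mean_iou": round(detection.mean_iou, 6),
            "iou_threshold": 0.5,
            "n_ground_truth": detection.n_ground_truth,
        },
        "prevalence": [{"variable": p.variable, "count_yes": p.count_yes,
                        "count_no": p.count_no, "percent_yes": p.percent_yes}
                       for p in prevalence],
        "signs": [_row_dict(r) for r in rows],
        "mean": _row_dict(mean_row),
    }
    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    table = pd.DataFrame([{k: d[k] for k in ("sign", "auroc", "sensitivity", "specificity", "f1")}
                          for d in report["signs"] + [report["mean"]]])
    table.to_csv(run_dir / "report_table.csv", index=False)
    return report


def run_pipeline(config: PipelineConfig, run_dir) -> dict:
    """Execute every stage in order; returns the report dict.

    The effective config and tool version are echoed to ``config.yaml`` in
    the run directory; ``report.json`` is byte-reproducible from
    (config, seed).
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.yaml", "w") as fh:
        yaml.safe_dump({"tool_version": __version__, **config.to_dict()}, fh, sort_keys=True)
    logger.info("stage=simulate n_patients=%d", config.n_patients)
    manifest = stage_simulate(config, run_dir)
    detection = None
    segmented = None
    if not config.use_ground_truth_masks:
        logger.info("stage=detect")
        boxes = stage_detect(config, run_dir, manifest)
        detection = _detection_result(manifest, boxes)
        logger.info("stage=crop")
        crops = stage_crop(config, run_dir, boxes)
        logger.info("stage=segment")
        segmented = stage_segment(config, run_dir, crops)
    logger.info("stage=motility mode=%s",
                "ground-truth" if config.use_ground_truth_masks else "segmented")
    motility_patients = stage_motility(config, run_dir, manifest, segmented)
    logger.info("stage=signs")
    scores = stage_signs(config, run_dir, manifest, segmented, motility_patients)
    logger.info("stage=evaluate")
    report = stage_evaluate(config, run_dir, manifest, scores, detection)
    logger.info("run complete: %s", run_dir / "report.json")
    return report
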