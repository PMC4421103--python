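"""End-to-end orchestration: segmentation -> features -> selection -> nets.

``run_train`` executes the four method stages in order on a training
cohort (phantoms by default, or user-supplied images with expert masks)
and persists every artifact; ``run_classify`` applies a trained
ensemble to new images.  ``run_benchmark`` is the seeded synthetic
experiment: a cohort of tumor-bearing phantoms is split train/test,
training uses ground-truth (expert-role) masks, testing segments
algorithmically, and the report aggregates one-vs-rest panels and
per-tissue Dice overlap.

All randomness descends from one top-level seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as iio
from .features import FEATURE_NAMES, BlockSpec, FeatureVector, image_features
from .ffbnn import (ClassifierEnsemble, TrainingConfig, classify,
                    ensemble_from_json, ensemble_to_json, fit_ensemble)
from .ipso import SwarmConfig, run_ipso
from .metrics import (ConfusionStats, aggregate, confusion, derive_stats,
                      dice_coefficient, render_panels)
from .phantom import (TISSUE_CLASSES, LabeledImage, PhantomSpec,
                      generate_phantom, random_tumor_spec)
from .preprocess import skull_strip
from .segmentation import SegmentationParams, segment_tissues

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; a single seed derives all module seeds."""

    seed: int = 0
    out_dir: Optional[str] = None
    n_train: int = 20
    n_test: int = 10
    noise_sd: float = 4.0
    image_size: int = 192
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    blocks: BlockSpec = field(default_factory=BlockSpec)
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    objective: str = "eq9"
    log_level: str = "INFO"


def derive_seeds(seed: int, n: int) -> List[int]:
    """Deterministic child seeds (each < 2**31) from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_cohort(cfg: RunConfig) -> List[LabeledImage]:
    """Seeded tumor-bearing phantoms, lesion geometry varying per slice."""
    seeds = derive_seeds(cfg.seed, cfg.n_train + cfg.n_test)
    base = PhantomSpec(width=cfg.image_size, height=cfg.image_size,
                       noise_sd=cfg.noise_sd, skull_ring=True)
    cohort = []
    for s in seeds:
        rng = np.random.default_rng(s)
        spec = random_tumor_spec(base, rng)
        spec = dataclasses.replace(spec, seed=s)
        cohort.append(generate_phantom(spec))
    return cohort


def ground_truth_masks(img: LabeledImage) -> Dict[str, np.ndarray]:
    return {c: img.mask(c) for c in TISSUE_CLASSES}


def features_table(rows: List[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["image_id", "tissue", *FEATURE_NAMES])


def _feature_rows(image_id, I_s, masks, blocks: BlockSpec) -> List[dict]:
    feats = image_features(I_s, masks, blocks)
    rows = []
    for tissue in TISSUE_CLASSES:
        if tissue in feats:
            fv = feats[tissue]
            rows.append({"image_id": image_id, "tissue": tissue,
                         **{n: getattr(fv, n) for n in FEATURE_NAMES}})
    return rows


@dataclass
class TrainResult:
    ensemble: ClassifierEnsemble
    selected: Dict[str, list]
    feature_table: pd.DataFrame
    train_accuracy: float = 0.0
    report: Optional[str] = None
    artifacts: Dict[str, str] = field(default_factory=dict)


def _evaluate_units(table: pd.DataFrame, ensemble: ClassifierEnsemble):
    """Per-image one-vs-rest panels over the tissue units of a table."""
    per_tissue: Dict[str, List[ConfusionStats]] = {c: [] for c in TISSUE_CLASSES}
    n_units = n_correct = 0
    for _, group in table.groupby("image_id", sort=False):
        y_true = list(group["tissue"])
        y_pred = [classify(ensemble, FeatureVector(*row))
                  for row in group[list(FEATURE_NAMES)].itertuples(index=False)]
        n_units += len(y_true)
        n_correct += sum(t == p for t, p in zip(y_true, y_pred))
        for c in TISSUE_CLASSES:
            if c in set(y_true) | set(y_pred):
                per_tissue[c].append(derive_stats(*confusion(y_true, y_pred, c)))
    per_tissue = {c: v for c, v in per_tissue.items() if v}
    acc = 100.0 * n_correct / n_units if n_units else 0.0
    return per_tissue, acc


def run_train(cfg: RunConfig,
              images: Optional[List[LabeledImage]] = None) -> TrainResult:
    """Stages in method order: segmentation, features, selection, training.

    Training images carry expert (ground-truth) tissue masks — for
    phantoms the generator's label map plays that role.  Artifacts
    (masks, features.csv, selected.json, model.json, report.csv) are
    persisted when ``cfg.out_dir`` is set.
    """
    logging.basicConfig(level=cfg.log_level)
    if images is None:
        images = make_cohort(cfg)[: cfg.n_train]
    if not images:
        raise ValueError("no training images")

    seeds = derive_seeds(cfg.seed + 1, 2 + len(TISSUE_CLASSES))
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)

    rows = []
    for i, img in enumerate(images):
        try:
            stripped = skull_strip(img.intensity)
            masks = ground_truth_masks(img)
            rows.extend(_feature_rows(i, stripped, masks, cfg.blocks))
            if out:
                for tissue, m in masks.items():
                    iio.save_mask(out / "masks" / f"train{i:03d}_{tissue}.png", m)
        except ValueError as exc:
            raise RuntimeError(f"stage segmentation/features failed on image {i}: {exc}")
    table = features_table(rows)

    selected = {}
    traces = {}
    for k, tissue in enumerate(TISSUE_CLASSES):
        scfg = dataclasses.replace(cfg.swarm, seed=seeds[2 + k])
        res = run_ipso(table, scfg, objective=cfg.objective, target_class=tissue)
        selected[tissue] = res.selected or list(FEATURE_NAMES)
        traces[tissue] = res.trace
        logger.info("selected for %s: %s (fitness %.4f)",
                    tissue, selected[tissue], res.best_fitness)

    tcfg = dataclasses.replace(cfg.training, seed=seeds[0])
    ensemble = fit_ensemble(table, selected, tcfg)

    panels, train_acc = _evaluate_units(table, ensemble)
    report = render_panels(panels)

    artifacts = {}
    if out:
        table.to_csv(out / "features.csv", index=False)
        (out / "selected.json").write_text(
            json.dumps(selected, indent=1, sort_keys=True))
        (out / "model.json").write_text(ensemble_to_json(ensemble))
        pd.DataFrame(traces).to_csv(out / "fitness_trace.csv", index=False)
        (out / "report.csv").write_text(report)
        artifacts = {k: str(out / v) for k, v in
                     [("features", "features.csv"), ("selected", "selected.json"),
                      ("model", "model.json"), ("trace", "fitness_trace.csv"),
                      ("report", "report.csv"), ("masks", "masks")]}
    return TrainResult(ensemble=ensemble, selected=selected,
                       feature_table=table, train_accuracy=train_acc,
                       report=report, artifacts=artifacts)


def segment_and_classify(
    img_intensity: np.ndarray,
    ensemble: ClassifierEnsemble,
    cfg: RunConfig,
    seed: int = 0,
) -> dict:
    """Strip, segment algorithmically, extract features, classify.

    Returns per-tissue predicted labels plus the masks; tissues whose
    region is absent/too small are reported absent, not an error.
    """
    stripped = skull_strip(img_intensity)
    masks = segment_tissues(stripped, cfg.seg, seed=seed)
    feats = image_features(stripped, masks.as_dict(), cfg.blocks)
    predictions = {t: classify(ensemble, fv) for t, fv in feats.items()}
    return {"masks": masks, "features": feats, "predictions": predictions,
            "absent": [t for t in TISSUE_CLASSES if t not in feats]}


def run_classify(cfg: RunConfig, ensemble: ClassifierEnsemble,
                 images: List[LabeledImage]) -> dict:
    """Classify a set of images; returns predictions, panels and report."""
    seeds = derive_seeds(cfg.seed + 2, len(images))
    results = []
    for i, img in enumerate(images):
        res = segment_and_classify(img.intensity, ensemble, cfg, seed=seeds[i])
        results.append(res)

    per_tissue: Dict[str, List[ConfusionStats]] = {c: [] for c in TISSUE_CLASSES}
    n_units = n_correct = 0
    for img, res in zip(images, results):
        present = [t for t in TISSUE_CLASSES if t in res["predictions"]]
        y_true = present
        y_pred = [res["predictions"][t] for t in present]
        n_units += len(present)
        n_correct += sum(t == p for t, p in zip(y_true, y_pred))
        for c in TISSUE_CLASSES:
            if c in set(y_true) | set(y_pred):
                per_tissue[c].append(derive_stats(*confusion(y_true, y_pred, c)))
    per_tissue = {c: v for c, v in per_tissue.items() if v}
    report = render_panels(per_tissue)
    overall = 100.0 * n_correct / n_units if n_units else 0.0
    return {"results": results, "panels": per_tissue, "report": report,
            "overall_accuracy": overall, "n_units": n_units}


def run_benchmark(seed: int = 0, n_train: int = 20, n_test: int = 10,
                  noise_sd: float = 4.0, out_dir: Optional[str] = None,
                  cfg: Optional[RunConfig] = None) -> dict:
    """The seeded synthetic experiment used for acceptance reporting.

    Trains on ``n_train`` phantoms (ground-truth masks in the expert
    role), tests on ``n_test`` held-out phantoms segmented
    algorithmically, and returns overall accuracy, mean per-tissue Dice
    against ground truth, and mean panel ACC/sensitivity/specificity.
    """
    if cfg is None:
        cfg = RunConfig(seed=seed, n_train=n_train, n_test=n_test,
                        noise_sd=noise_sd, out_dir=out_dir)
    cohort = make_cohort(cfg)
    train_imgs, test_imgs = cohort[: cfg.n_train], cohort[cfg.n_train :]

    tr = run_train(cfg, images=train_imgs)
    cl = run_classify(cfg, tr.ensemble, test_imgs)

    dice: Dict[str, List[float]] = {c: [] for c in TISSUE_CLASSES}
    for img, res in zip(test_imgs, cl["results"]):
        pred = res["masks"].as_dict()
        for c in TISSUE_CLASSES:
            dice[c].append(dice_coefficient(pred[c], img.mask(c)))
    mean_dice = {c: float(np.mean(v)) for c, v in dice.items()}

    allstats = [s for rows in cl["panels"].values() for s in rows]
    summary = {
        "overall_accuracy": cl["overall_accuracy"],
        "n_units": cl["n_units"],
        "mean_dice": mean_dice,
        "mean_acc": aggregate(allstats, "acc"),
        "mean_sensitivity": aggregate(allstats, "sensitivity"),
        "mean_specificity": aggregate(allstats, "specificity"),
        "selected": tr.selected,
        "report": cl["report"],
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        (out / "report.csv").write_text(cl["report"])
        payload = {k: v for k, v in summary.items() if k != "report"}
        (out / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return summary
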