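"""End-to-end training, inference and case-level cross-validation.

Training: histogram-match every case to the reference, normalize to [0,1],
SLIC-partition each slice, fit the texton model on pooled training
responses, extract the 28-feature descriptor per superpixel, fit the
[0,30] scaling, rank features by mRMR with leave-one-case-out voting (or
use the named preset), and train the extra-trees ensemble. The result is a
single-file model bundle that carries everything inference needs,
including the reference intensities for histogram matching.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from flairseg.config import PipelineConfig
from flairseg.ert_classifier import ERTModel, ert_train
from flairseg.evaluation import ClassificationMetrics, EvalReport, classification_metrics, dice
from flairseg.feature_select import PRESET_FEATURES, mrmr_rank, vote_select
from flairseg.io_preprocess import Volume, _quantile_map, normalize_unit
from flairseg.segment_postprocess import (
    SegmentationMask,
    filter_components_3d,
    label_superpixels,
    mask_from_predictions,
)
from flairseg.superpixel import SuperpixelMap, segment_volume
from flairseg.texture_features import (
    FEATURE_COLUMNS,
    GaborBank,
    TextonModel,
    assemble_and_scale,
    extract_case_features,
    filter_responses,
    texton_fit_vectors,
)

logger = logging.getLogger("flairseg")

BUNDLE_VERSION = 1

__all__ = ["ModelBundle", "run_training", "run_inference", "crossval", "save_bundle", "load_bundle"]


@dataclass
class ModelBundle:
    """Everything inference needs, serializable to a single file."""

    version: int
    config: PipelineConfig
    bank: GaborBank
    texton_model: TextonModel
    scale_lo: pd.Series
    scale_hi: pd.Series
    selected_features: list[str]
    ert: ERTModel
    reference_values: np.ndarray  # within-mask intensities of the reference case
    selection_report: dict = field(default_factory=dict)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    joblib.dump(bundle, path)


def load_bundle(path: str | Path) -> ModelBundle:
    bundle = joblib.load(path)
    if bundle.version != BUNDLE_VERSION:
        raise ValueError(f"incompatible bundle version {bundle.version}")
    return bundle


def _match_to_reference(vol: Volume, reference_values: np.ndarray) -> Volume:
    from dataclasses import replace

    src = vol.masked_values
    out = vol.data.copy()
    out[vol.brain_mask] = _quantile_map(src, src, reference_values, 256, 100)
    return replace(vol, data=out)


def _preprocess(vol: Volume, reference_values: np.ndarray) -> Volume:
    return normalize_unit(_match_to_reference(vol, reference_values))


def _bank_from_config(cfg: PipelineConfig) -> GaborBank:
    t = cfg.texton
    return GaborBank(thetas=tuple(t.thetas), sigmas=tuple(t.sigmas),
                     lambdas=tuple(t.lambdas), psi=t.psi, gamma=t.gamma)


def _texton_training_vectors(images: list[np.ndarray], masks: list[np.ndarray],
                             bank: GaborBank, budget: int, seed: int) -> np.ndarray:
    """Subsample within-mask response vectors slice by slice to bound memory."""
    rng = np.random.default_rng(seed)
    per_slice = max(200, budget // max(1, sum(int(m.any()) for msk in masks for m in msk)))
    chunks = []
    for image, mask in zip(images, masks):
        for z in range(image.shape[0]):
            if not mask[z].any():
                continue
            resp = filter_responses(image[z], bank)
            vecs = resp[mask[z]]
            if vecs.shape[0] > per_slice:
                vecs = vecs[rng.choice(vecs.shape[0], per_slice, replace=False)]
            chunks.append(vecs)
    return np.concatenate(chunks, axis=0)


def run_training(cases: list[tuple[Volume, np.ndarray]], config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> ModelBundle:
    """Train the full pipeline on (volume, ground-truth mask) pairs."""
    cfg = config or PipelineConfig()
    if len(cases) < 2:
        raise ValueError("training requires at least 2 cases with ground truth")
    for vol, gt in cases:
        if gt is None:
            raise ValueError(f"case {vol.case_id!r} is missing its ground-truth mask")
        if gt.shape != vol.data.shape:
            raise ValueError(f"case {vol.case_id!r}: ground-truth shape mismatch")

    ref_idx = 0
    if cfg.reference_case is not None:
        ids = [v.case_id for v, _ in cases]
        ref_idx = ids.index(cfg.reference_case)
    reference_values = cases[ref_idx][0].masked_values.copy()

    logger.info("preprocessing %d cases (reference %s)", len(cases), cases[ref_idx][0].case_id)
    pre = [_preprocess(vol, reference_values) for vol, _ in cases]

    sp = cfg.superpixel
    spx_maps = [
        segment_volume(v.data, v.brain_mask, S=sp.S, m=sp.m, n_iter=sp.n_iter, case_id=v.case_id)
        for v in pre
    ]

    bank = _bank_from_config(cfg)
    logger.info("fitting texton model (k=%d, %d filters)", cfg.texton.k, bank.n_filters)
    X_tex = _texton_training_vectors([v.data for v in pre], [v.brain_mask for v in pre],
                                     bank, cfg.texton.max_pixels, cfg.seed)
    texton_model = texton_fit_vectors(X_tex, k=cfg.texton.k, seed=cfg.seed,
                                      max_pixels=cfg.texton.max_pixels)

    frames, labels = [], []
    for v, spx, (_, gt) in zip(pre, spx_maps, cases):
        frame = extract_case_features(v.data, spx, bank, texton_model, case_id=v.case_id,
                                      n_t=cfg.features.n_t,
                                      curvature_sigma=cfg.features.curvature_sigma)
        lab = label_superpixels(gt, spx)
        logger.info("case %s: %d superpixels, %.1f%% tumour", v.case_id, len(lab),
                    100.0 * lab.mean() if len(lab) else 0.0)
        frames.append(frame)
        labels.append(lab)
    all_rows = pd.concat(frames, ignore_index=True)
    y = np.concatenate(labels)

    fm = assemble_and_scale(all_rows, fit=True, scale_max=cfg.features.scale_hi)

    sel = cfg.select
    selection_report: dict = {}
    if sel.use_preset:
        selected = list(PRESET_FEATURES)
        selection_report["preset"] = selected
    else:
        case_ids = fm.frame["case"].to_numpy()
        fold_rankings = []
        for held_out in dict.fromkeys(case_ids):
            keep = case_ids != held_out
            if y[keep].min() == y[keep].max():
                continue  # fold without both classes carries no signal
            idx = mrmr_rank(fm.frame.loc[keep, FEATURE_COLUMNS], y[keep],
                            n_select=sel.n_fea, n_bins=sel.n_bins, scheme=sel.scheme)
            fold_rankings.append([FEATURE_COLUMNS[i] for i in idx])
        selected = vote_select(fold_rankings, n_fea=sel.n_fea)
        selection_report = {
            "per_fold_rankings": fold_rankings,
            "final": selected,
        }
    logger.info("selected features: %s", selected)

    e = cfg.ert
    ert = ert_train(fm.frame[selected].to_numpy(), y, T=e.T, K=min(e.K, len(selected)),
                    n_min=e.n_min, max_depth=e.max_depth, seed=cfg.seed,
                    criterion=e.criterion, class_weight=e.class_weight)

    bundle = ModelBundle(
        version=BUNDLE_VERSION, config=cfg, bank=bank, texton_model=texton_model,
        scale_lo=fm.scale_lo, scale_hi=fm.scale_hi, selected_features=list(selected),
        ert=ert, reference_values=reference_values, selection_report=selection_report,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_bundle(bundle, out_dir / "model_bundle.joblib")
        cfg.to_yaml(out_dir / "config.yaml")
        (out_dir / "selection_report.json").write_text(json.dumps(selection_report, indent=2))
        fm.to_csv(out_dir / "training_features.csv")
    return bundle


def _case_features(bundle: ModelBundle, vol: Volume) -> tuple[SuperpixelMap, pd.DataFrame]:
    cfg = bundle.config
    pre = _preprocess(vol, bundle.reference_values)
    sp = cfg.superpixel
    spx = segment_volume(pre.data, pre.brain_mask, S=sp.S, m=sp.m, n_iter=sp.n_iter,
                         case_id=vol.case_id)
    frame = extract_case_features(pre.data, spx, bundle.bank, bundle.texton_model,
                                  case_id=vol.case_id, n_t=cfg.features.n_t,
                                  curvature_sigma=cfg.features.curvature_sigma)
    fm = assemble_and_scale(frame, fit=False, scale_params=(bundle.scale_lo, bundle.scale_hi),
                            scale_max=cfg.features.scale_hi)
    return spx, fm.frame


def run_inference(bundle: ModelBundle, vol: Volume, gt_mask: np.ndarray | None = None
                  ) -> tuple[SegmentationMask, dict | None]:
    """Segment one volume; optionally evaluate against a ground-truth mask.

    Returns the filtered 3D mask and, when ground truth is given, a dict
    with superpixel-level precision/sensitivity/BER and voxel-level Dice.
    """
    if not vol.brain_mask.any():
        raise ValueError("inference requires a nonempty brain mask")
    spx, frame = _case_features(bundle, vol)
    X = frame[bundle.selected_features].to_numpy()
    if X.shape[1] != bundle.ert.n_features:
        raise ValueError("feature-dimension mismatch at classification stage")
    proba = bundle.ert.estimator.predict_proba(X)
    pos = int(np.nonzero(bundle.ert.classes_ == 1)[0][0])
    pred = (proba[:, pos] >= bundle.config.postprocess.threshold).astype(int)
    raw_mask = mask_from_predictions(spx, pred)
    seg = filter_components_3d(raw_mask, min_voxels=bundle.config.postprocess.min_region_voxels,
                               connectivity=bundle.config.postprocess.connectivity)
    report = None
    if gt_mask is not None:
        truth = label_superpixels(gt_mask, spx)
        cm: ClassificationMetrics = classification_metrics(pred, truth)
        report = {
            "precision": cm.precision,
            "sensitivity": cm.sensitivity,
            "ber": cm.ber,
            "dice": dice(seg.mask, gt_mask),
        }
    return seg, report


def crossval(cases: list[tuple[Volume, np.ndarray]], config: PipelineConfig | None = None
             ) -> EvalReport:
    """Leave-one-case-out cross-validation over a cohort."""
    cfg = config or PipelineConfig()
    report = EvalReport()
    for i, (vol, gt) in enumerate(cases):
        train_cases = cases[:i] + cases[i + 1 :]
        bundle = run_training(train_cases, cfg)
        _, metrics = run_inference(bundle, vol, gt)
        report.add_case(vol.case_id,
                        ClassificationMetrics(metrics["precision"], metrics["sensitivity"],
                                              metrics["ber"]),
                        metrics["dice"])
    return report
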