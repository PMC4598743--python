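"""Segmentation quality metrics and end-to-end pipeline orchestration.

Segmentation is scored by the 2-D correlation coefficient between the
binary indicator image of a predicted region and that of the reference
region, computed separately for nucleus and cytoplasm.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sdmclust import classify as clf
from sdmclust.clustering import GaConfig, segment
from sdmclust.features import ALL_FEATURE_NAMES, extract_all, scale_features
from sdmclust.imaging import CYTOPLASM, NUCLEUS, read_image, read_mask, rgb_to_cielab, write_mask

log = logging.getLogger("sdmclust")


@dataclass
class SegmentationScore:
    corr_nucleus: float
    corr_cytoplasm: float
    degenerate: bool = False


def correlation2d(Y: np.ndarray, T: np.ndarray) -> float:
    """Pearson correlation of two images over all pixels:
    sum((Y-Ybar)(T-Tbar)) / sqrt(sum((Y-Ybar)^2) sum((T-Tbar)^2)).

    Identical constant images correlate perfectly (1.0); if exactly one
    input is constant the correlation is undefined and reported as 0.
    """
    Y = np.asarray(Y, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if Y.shape != T.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {T.shape}")
    dy = Y - Y.mean()
    dt = T - T.mean()
    sy = float(np.sum(dy * dy))
    st = float(np.sum(dt * dt))
    if sy == 0 and st == 0:
        if np.array_equal(Y, T):
            return 1.0
        raise ValueError("both images constant but unequal; correlation undefined")
    if sy == 0 or st == 0:
        return 0.0
    return float(np.sum(dy * dt) / np.sqrt(sy * st))


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegmentationScore:
    """Correlation on the nucleus and cytoplasm indicator images."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    scores = {}
    degenerate = False
    for role, key in ((NUCLEUS, "nucleus"), (CYTOPLASM, "cytoplasm")):
        y = pred == role
        t = truth == role
        if y.std() == 0 or t.std() == 0:
            degenerate = True
            scores[key] = 1.0 if np.array_equal(y, t) else 0.0
        else:
            scores[key] = correlation2d(y, t)
    return SegmentationScore(corr_nucleus=scores["nucleus"],
                             corr_cytoplasm=scores["cytoplasm"], degenerate=degenerate)


def _stage_seed(root: int, stage: str, index: int = 0) -> int:
    """Named substream: each stage draws from its own child of the root seed."""
    h = np.random.SeedSequence([root, zlib.crc32(stage.encode()), index])
    return int(h.generate_state(1)[0] >> 1)


def run_pipeline(manifest: str | os.PathLike | pd.DataFrame, config: dict | None = None,
                 out_dir: str | os.PathLike | None = None) -> dict:
    """Segment, featurise and (optionally) validate a dataset of cell images.

    ``manifest`` is a CSV or DataFrame with columns ``image_path``
    (required), ``truth_path`` and ``label`` (optional).  For each image:
    GA threshold clustering on L*, role assignment, morphological
    refinement, feature extraction; then, if labels are present, the
    requested validation protocol.  The whole run is reproducible from
    ``config['seed']`` via named per-stage substreams.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    objective = config.get("objective", "SDM")
    validate = config.get("validate")  # holdout75 | holdout50 | holdout25 | cv10 | boot632
    model_kind = config.get("model", "svm")
    morph = bool(config.get("morphology", True))

    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
    else:
        df = pd.read_csv(manifest)
    if df.empty:
        raise ValueError("empty manifest")
    if "image_path" not in df.columns:
        raise ValueError("manifest needs an 'image_path' column")

    out = Path(out_dir) if out_dir else None
    if out:
        (out / "masks").mkdir(parents=True, exist_ok=True)

    rows, feats, labels, failures = [], [], [], 0
    for i, rec in df.reset_index(drop=True).iterrows():
        try:
            img = read_image(rec["image_path"])
            lab = rgb_to_cielab(img)
            cfg = GaConfig(objective=objective, seed=_stage_seed(seed, "segment", i),
                           **config.get("ga", {}))
            mask, chrom, trace = segment(lab.L, cfg, morphology_refine=morph)
            fv = extract_all(lab, mask)
            row = {"image_path": rec["image_path"], "t1": chrom.t1, "t2": chrom.t2,
                   "final_fitness": trace[-1]}
            if isinstance(rec.get("truth_path"), str) and rec.get("truth_path"):
                score = evaluate_segmentation(mask, read_mask(rec["truth_path"]))
                row["corr_nucleus"] = score.corr_nucleus
                row["corr_cytoplasm"] = score.corr_cytoplasm
            if out:
                mask_path = out / "masks" / (Path(str(rec["image_path"])).stem + "_mask.png")
                write_mask(mask, mask_path)
                row["mask_path"] = str(mask_path)
            rows.append(row)
            feats.append(fv.values)
            if "label" in df.columns and not pd.isna(rec.get("label")):
                labels.append(str(rec["label"]))
        except Exception as exc:
            failures += 1
            log.warning("image %s failed: %s", rec.get("image_path"), exc)

    if not rows:
        raise RuntimeError("every image failed")
    report = {"seed": seed, "objective": objective, "n_images": len(rows),
              "n_failures": failures, "per_image": rows}
    X = np.vstack(feats)
    feat_df = pd.DataFrame(X, columns=ALL_FEATURE_NAMES)

    if "corr_nucleus" in rows[0]:
        report["mean_corr_nucleus"] = float(np.mean([r["corr_nucleus"] for r in rows]))
        report["mean_corr_cytoplasm"] = float(np.mean([r["corr_cytoplasm"] for r in rows]))

    if validate and len(labels) == len(rows):
        y = (np.array(labels) == "blast").astype(int)
        Xs, _, _ = scale_features(X)
        factory = lambda s: clf.make_model(model_kind, seed=s)
        vseed = _stage_seed(seed, "validate")
        if validate.startswith("holdout"):
            scheme = {"holdout75": "75:25", "holdout50": "50:50", "holdout25": "25:75"}[validate]
            report["validation"] = clf.holdout_eval(Xs, y, scheme, factory, seed=vseed)
        elif validate == "cv10":
            report["validation"] = clf.kfold_cv(Xs, y, factory, k=10, seed=vseed)
        elif validate == "boot632":
            rep = clf.bootstrap_632(Xs, y, factory, b=int(config.get("b", 500)), seed=vseed)
            report["validation"] = {"b": rep.b, "acc_boot": rep.acc_boot,
                                    "oob_fraction": rep.oob_fraction}
        else:
            raise ValueError(f"unknown validation protocol {validate!r}")

    if out:
        feat_df.to_csv(out / "features.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    report["features"] = feat_df
    return report
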