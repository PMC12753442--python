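"""Classification metrics: confusion-matrix ACC/SE/SP and ROC/AUC, plus
the modality-ablation report."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "ConfusionCounts", "RocCurve", "UndefinedMetricError",
    "confusion_from_pairs", "confusion_metrics", "roc_auc",
    "ablation_table",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero for the evaluated sample."""


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_from_pairs(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    if not np.isin(labels, (0, 1)).all() or not np.isin(predictions, (0, 1)).all():
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """ACC = (TP+TN)/n, SE = TP/(TP+FN), SP = TN/(TN+FP), as percentages."""
    if counts.total == 0:
        raise UndefinedMetricError("ACC undefined: no evaluated samples")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("SE undefined: no positive samples")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("SP undefined: no negative samples")
    return {
        "ACC": 100.0 * (counts.tp + counts.tn) / counts.total,
        "SE": 100.0 * counts.tp / (counts.tp + counts.fn),
        "SP": 100.0 * counts.tn / (counts.tn + counts.fp),
    }


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over all score thresholds with trapezoidal AUC.

    With the half-credit tie convention this AUC equals the pairwise
    concordance probability P(score_pos > score_neg) + 0.5 P(equal).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(_skm.auc(fpr, tpr)))


def ablation_table(cohort, configs: list[dict], seeds: list[int],
                   train_config=None, encoder_config=None,
                   contrastive_config=None, eval_cohort=None) -> pd.DataFrame:
    """Train/evaluate one pipeline per (config, seed) and tabulate.

    Each config is a dict with keys ``modalities`` (subset of
    ``("ct", "us", "clinical")``) and ``contrastive`` (bool).  Emits one
    row per (config, seed) plus a seed-mean row per config, with
    checkmark columns per modality and ACC/SE/SP/AUC as percentages.
    When ``eval_cohort`` is given, its records are scored as an extra
    held-out set and its AUC reported in ``AUC_eval``.
    """
    from .training import TrainConfig, evaluate_checkpoint, split_cohort, train
    from .encoders import EncoderConfig
    from .contrastive import ContrastiveConfig

    train_config = train_config or TrainConfig()
    encoder_config = encoder_config or EncoderConfig()
    contrastive_config = contrastive_config or ContrastiveConfig()
    rows = []
    for cfg in configs:
        modalities = tuple(cfg["modalities"])
        use_contrastive = bool(cfg.get("contrastive", False))
        per_seed = []
        for seed in seeds:
            tc = dataclasses.replace(train_config, seed=int(seed))
            try:
                split = split_cohort(cohort, seed=int(seed))
                ckpt = train(cohort, split, tc, encoder_config,
                             contrastive_config, modalities=modalities,
                             use_contrastive=use_contrastive)
                test_records = [cohort.records[i] for i in split.test_ids]
                result = evaluate_checkpoint(ckpt, test_records)
                row = {"seed": seed, **result}
                if eval_cohort is not None:
                    ext = evaluate_checkpoint(ckpt, eval_cohort.records)
                    row["AUC_eval"] = ext["AUC"]
                per_seed.append(row)
            except Exception as exc:   # annotate, keep the table going
                per_seed.append({"seed": seed, "error": str(exc)})
        flags = {"CT": "ct" in modalities, "US": "us" in modalities,
                 "Clinical": "clinical" in modalities,
                 "Contrastive": use_contrastive}
        for row in per_seed:
            rows.append({**flags, **row})
        ok = [r for r in per_seed if "error" not in r]
        if ok:
            mean_row = {**flags, "seed": "mean"}
            for key in ("ACC", "SE", "SP", "AUC", "AUC_eval"):
                vals = [r[key] for r in ok if key in r]
                if vals:
                    mean_row[key] = float(np.mean(vals))
            rows.append(mean_row)
    return pd.DataFrame(rows)
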