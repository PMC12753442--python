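"""Joint training of the multi-modal LNM classifier.

Implements concatenation fusion of the 512-d modality features, a
binary classifier on the fused vector, the joint objective
total = cross-entropy + combined contrastive loss, the stratified
80/10/10 cohort split, inverse-class-frequency weighted mini-batch
sampling, Adam with cosine-annealed learning rate, and checkpoint
selection by highest validation accuracy (ties resolved toward the
earliest epoch).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .clinical import (DEFAULT_FEATURES, apply_normalizer, clinical_matrix,
                       fit_normalizer)
from .cohort import Cohort
from .contrastive import (CombinedLoss, ContrastiveConfig, ProjectionBundle,
                          ProjectionHead, combined_contrastive)
from .encoders import (ClinicalEncoder, EncoderConfig, ImageEncoder,
                       random_crop_resize)
from .evaluation import confusion_from_pairs, confusion_metrics, roc_auc
from .nn import Adam, Linear, Module, Tensor, cosine_annealing_lr

__all__ = [
    "LossBreakdown", "SplitAssignment", "TrainConfig", "Checkpoint",
    "fuse", "classify", "total_loss", "split_cohort", "sampler_weights",
    "LNMModel", "train", "predict_scores", "evaluate_checkpoint",
    "save_checkpoint", "load_checkpoint",
]

MODALITIES = ("ct", "us", "clinical")


@dataclasses.dataclass
class LossBreakdown:
    """Scalar record of one objective evaluation.

    Invariants (asserted in training): ``contrastive`` is the mean of
    ``pair_losses`` and ``total = ce + contrastive`` exactly.
    """

    ce: float
    pair_losses: dict[str, float]
    contrastive: float
    total: float


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    class_weighting: bool = True

    def validate(self) -> None:
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 2:
            raise ValueError("lr must be > 0, epochs >= 1, batch_size >= 2")


@dataclasses.dataclass
class SplitAssignment:
    train_ids: list[int]
    val_ids: list[int]
    test_ids: list[int]
    seed: int
    stratified: bool


@dataclasses.dataclass
class Checkpoint:
    """Self-contained training result: weights + everything needed to
    evaluate (configs, normalization bounds, feature order)."""

    state: dict[str, np.ndarray]
    modalities: tuple[str, ...]
    use_contrastive: bool
    train_config: TrainConfig
    encoder_config: EncoderConfig
    contrastive_config: ContrastiveConfig
    bounds: np.ndarray | None
    feature_names: tuple[str, ...]
    best_epoch: int
    history: list[dict]


# ------------------------------------------------------------------ fusion

def fuse(h_list: list[Tensor]) -> Tensor:
    """Column-wise concatenation of modality features, in the fixed
    order ct || us || clinical (the order of `h_list`)."""
    if not h_list:
        raise ValueError("nothing to fuse")
    rows = {t.data.shape[0] for t in h_list}
    if len(rows) != 1:
        raise ValueError(f"row-count mismatch across modalities: {rows}")
    widths = {t.data.shape[1] for t in h_list}
    if len(widths) != 1:
        raise ValueError(f"feature-width mismatch across modalities: {widths}")
    return Tensor.cat(h_list, axis=1)


def classify(fused: Tensor, classifier: Linear) -> Tensor:
    """Binary class scores from the fused representation."""
    if fused.data.shape[1] != classifier.weight.data.shape[0]:
        raise ValueError(
            f"fused width {fused.data.shape[1]} does not match classifier "
            f"input {classifier.weight.data.shape[0]}")
    return classifier(fused)


def _log_softmax(scores: Tensor) -> Tensor:
    m = Tensor(scores.data.max(axis=1, keepdims=True))      # detached shift
    shifted = scores - m
    return shifted - shifted.exp().sum(axis=1, keepdims=True).log()


def total_loss(scores: Tensor, labels: np.ndarray,
               contrastive: CombinedLoss | None
               ) -> tuple[Tensor, LossBreakdown]:
    """Joint objective: mean cross-entropy plus the combined contrastive
    term (when present); total = ce + contrastive exactly."""
    labels = np.asarray(labels, dtype=int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n = scores.data.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must align with the score rows")
    logp = _log_softmax(scores)
    ce = -(logp[np.arange(n), labels].mean())
    if contrastive is None:
        total = ce
        pair = {}
        con_val = 0.0
    else:
        total = ce + contrastive.mean
        pair = {k: float(v.mean.data) for k, v in
                contrastive.pair_losses.items()}
        con_val = float(contrastive.mean.data)
    return total, LossBreakdown(ce=float(ce.data), pair_losses=pair,
                                contrastive=con_val, total=float(total.data))


# ------------------------------------------------------------------ splits

def _split_sizes(n: int) -> tuple[int, int, int]:
    """80/10/10 with train rounded to nearest and the remainder split
    floor(val)/rest(test); 127 -> (102, 12, 13)."""
    n_train = int(round(0.8 * n))
    rest = n - n_train
    n_val = rest // 2
    return n_train, n_val, rest - n_val


def split_cohort(cohort: Cohort, seed: int,
                 stratified: bool = True) -> SplitAssignment:
    """Random disjoint train/val/test partition (indices into
    ``cohort.records``); stratified mode preserves prevalence per split
    and guarantees at least one positive in val and test."""
    n = len(cohort)
    labels = cohort.labels
    if labels.sum() == 0 or labels.sum() == n:
        raise ValueError("cohort must contain both classes")
    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = _split_sizes(n)
    if not stratified:
        perm = rng.permutation(n)
        return SplitAssignment(
            train_ids=sorted(perm[:n_train].tolist()),
            val_ids=sorted(perm[n_train:n_train + n_val].tolist()),
            test_ids=sorted(perm[n_train + n_val:].tolist()),
            seed=seed, stratified=False)
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    p = len(pos)
    if p < 3:
        raise ValueError(
            f"stratified split needs >= 3 positives to place one in each "
            f"split, got {p}")
    p_train = int(round(0.8 * p))
    rest = p - p_train
    if rest < 2:
        p_train = p - 2
        rest = 2
    p_val = max(1, rest // 2)
    p_test = rest - p_val
    splits = {"train": [], "val": [], "test": []}
    splits["train"].extend(pos[:p_train])
    splits["val"].extend(pos[p_train:p_train + p_val])
    splits["test"].extend(pos[p_train + p_val:])
    # fill remaining slots with negatives
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    cursor = 0
    for name in ("train", "val", "test"):
        need = sizes[name] - len(splits[name])
        if need < 0:
            raise ValueError(f"cohort too small to stratify the {name} split")
        splits[name].extend(neg[cursor:cursor + need])
        cursor += need
    return SplitAssignment(
        train_ids=sorted(int(i) for i in splits["train"]),
        val_ids=sorted(int(i) for i in splits["val"]),
        test_ids=sorted(int(i) for i in splits["test"]),
        seed=seed, stratified=True)


def sampler_weights(labels) -> np.ndarray:
    """Per-record sampling probabilities proportional to the inverse
    class frequency; sums to 1 and draws each class with probability
    1/2 in expectation."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("weighted sampling needs both classes in the "
                         "training split")
    w = 1.0 / (2.0 * counts[labels])
    return w


# ------------------------------------------------------------------- model

class LNMModel(Module):
    """Encoders + projection heads + fused binary classifier for a
    configurable subset of modalities."""

    def __init__(self, modalities: tuple[str, ...], use_contrastive: bool,
                 n_clinical_features: int, encoder_config: EncoderConfig,
                 contrastive_config: ContrastiveConfig,
                 rng: np.random.Generator):
        super().__init__()
        modalities = tuple(m for m in MODALITIES if m in modalities)
        if not modalities:
            raise ValueError("at least one modality is required")
        if use_contrastive and len(modalities) < 2:
            raise ValueError("contrastive alignment needs >= 2 modalities")
        self.modalities = modalities
        self.use_contrastive = use_contrastive
        self.encoder_config = encoder_config
        self.contrastive_config = contrastive_config
        D = encoder_config.feature_dim
        self.enc_ct = self.enc_us = self.enc_clin = None
        self.head_ct = self.head_us = self.head_clin = None
        if "ct" in modalities:
            self.enc_ct = ImageEncoder(encoder_config, rng)
        if "us" in modalities:
            if encoder_config.share_image_backbone and self.enc_ct is not None:
                self.enc_us = self.enc_ct
            else:
                self.enc_us = ImageEncoder(encoder_config, rng)
        if "clinical" in modalities:
            self.enc_clin = ClinicalEncoder(n_clinical_features,
                                            encoder_config, rng)
        if use_contrastive:
            pdim = contrastive_config.projection_dim
            if "ct" in modalities:
                self.head_ct = ProjectionHead(D, rng, pdim)
            if "us" in modalities:
                self.head_us = ProjectionHead(D, rng, pdim)
            if "clinical" in modalities:
                self.head_clin = ProjectionHead(D, rng, pdim)
        self.classifier = Linear(D * len(modalities), 2, rng)

    def encode(self, batch: dict) -> dict[str, Tensor]:
        feats = {}
        if "ct" in self.modalities:
            feats["ct"] = self.enc_ct(batch["ct"])
        if "us" in self.modalities:
            feats["us"] = self.enc_us(batch["us"])
        if "clinical" in self.modalities:
            feats["clinical"] = self.enc_clin(batch["clinical"])
        return feats

    def forward(self, batch: dict) -> tuple[Tensor, ProjectionBundle | None]:
        feats = self.encode(batch)
        fused = fuse([feats[m] for m in self.modalities])
        scores = classify(fused, self.classifier)
        proj = None
        if self.use_contrastive:
            proj = ProjectionBundle(
                z_ct=self.head_ct(feats["ct"]) if "ct" in feats else None,
                z_us=self.head_us(feats["us"]) if "us" in feats else None,
                z_clin=(self.head_clin(feats["clinical"])
                        if "clinical" in feats else None))
        return scores, proj


# ---------------------------------------------------------------- training

def _prepare_batch(records, model: LNMModel, bounds, feature_names,
                   rng: np.random.Generator | None, training: bool) -> dict:
    batch: dict = {}
    cfg = model.encoder_config
    if "ct" in model.modalities:
        batch["ct"] = np.stack([
            random_crop_resize(r.ct_image, cfg, rng, training=training)
            for r in records]).astype(np.float32)
    if "us" in model.modalities:
        batch["us"] = np.stack([
            random_crop_resize(r.us_image, cfg, rng, training=training)
            for r in records]).astype(np.float32)
    if "clinical" in model.modalities:
        raw = clinical_matrix(records, feature_names)
        batch["clinical"] = apply_normalizer(raw, bounds).astype(np.float32)
    return batch


def _predict_proba(model: LNMModel, records, bounds, feature_names,
                   chunk: int = 32) -> np.ndarray:
    """Positive-class probability per record, evaluation mode."""
    model.eval()
    probs = []
    for start in range(0, len(records), chunk):
        part = records[start:start + chunk]
        batch = _prepare_batch(part, model, bounds, feature_names,
                               rng=None, training=False)
        scores, _ = model(batch)
        s = scores.data.astype(np.float64)
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        probs.append(e[:, 1] / e.sum(axis=1))
    return np.concatenate(probs)


def _hard_predictions(probs: np.ndarray) -> np.ndarray:
    # argmax of the two-class scores; exact ties resolve to the negative
    # class (probability must strictly exceed 1/2)
    return (probs > 0.5).astype(int)


def train(cohort: Cohort, split: SplitAssignment, train_config: TrainConfig,
          encoder_config: EncoderConfig,
          contrastive_config: ContrastiveConfig = ContrastiveConfig(),
          modalities: tuple[str, ...] = MODALITIES,
          use_contrastive: bool = True,
          feature_names: tuple[str, ...] = DEFAULT_FEATURES,
          log_file: str | Path | None = None) -> Checkpoint:
    """Run the joint optimization and return the checkpoint from the
    epoch with the highest validation accuracy."""
    train_config.validate()
    encoder_config.validate()
    contrastive_config.validate()
    train_records = [cohort.records[i] for i in split.train_ids]
    val_records = [cohort.records[i] for i in split.val_ids]
    train_labels = np.array([r.label for r in train_records])
    if len(set(train_labels.tolist())) < 2:
        raise ValueError("training split must contain both classes")

    bounds = None
    if "clinical" in modalities:
        bounds = fit_normalizer(clinical_matrix(train_records, feature_names))

    rng_init = np.random.default_rng([train_config.seed, 1])
    rng_sample = np.random.default_rng([train_config.seed, 2])
    rng_augment = np.random.default_rng([train_config.seed, 3])
    model = LNMModel(modalities, use_contrastive, len(feature_names),
                     encoder_config, contrastive_config, rng_init)
    optimizer = Adam(model.parameters(), lr=train_config.lr)
    probs = (sampler_weights(train_labels)
             if train_config.class_weighting else None)

    n_batches = math.ceil(len(train_records) / train_config.batch_size)
    best_acc, best_epoch, best_state = -np.inf, -1, None
    history: list[dict] = []
    log_fh = open(log_file, "w") if log_file else None
    try:
        for epoch in range(train_config.epochs):
            lr = cosine_annealing_lr(train_config.lr, epoch,
                                     train_config.epochs)
            optimizer.lr = lr
            model.train()
            epoch_losses: list[LossBreakdown] = []
            for _ in range(n_batches):
                idx = rng_sample.choice(len(train_records),
                                        size=train_config.batch_size,
                                        replace=True, p=probs)
                records = [train_records[i] for i in idx]
                batch = _prepare_batch(records, model, bounds, feature_names,
                                       rng_augment, training=True)
                labels = np.array([r.label for r in records])
                scores, proj = model(batch)
                con = (combined_contrastive(proj, contrastive_config)
                       if proj is not None else None)
                total, breakdown = total_loss(scores, labels, con)
                if not math.isfinite(breakdown.total):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: "
                        f"non-finite loss {breakdown}")
                model.zero_grad()
                total.backward()
                optimizer.step()
                epoch_losses.append(breakdown)
            val_probs = _predict_proba(model, val_records, bounds,
                                       feature_names)
            val_labels = np.array([r.label for r in val_records])
            val_acc = float((_hard_predictions(val_probs)
                             == val_labels).mean())
            entry = {
                "epoch": epoch,
                "lr": float(lr),
                "ce": float(np.mean([b.ce for b in epoch_losses])),
                "contrastive": float(np.mean([b.contrastive
                                              for b in epoch_losses])),
                "pair_losses": {
                    k: float(np.mean([b.pair_losses[k]
                                      for b in epoch_losses]))
                    for k in epoch_losses[0].pair_losses},
                "total": float(np.mean([b.total for b in epoch_losses])),
                "val_acc": val_acc,
            }
            history.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
            if val_acc > best_acc:      # strict: ties keep earliest epoch
                best_acc, best_epoch = val_acc, epoch
                best_state = {k: v.copy()
                              for k, v in model.state_dict().items()}
    finally:
        if log_fh:
            log_fh.close()
    model.load_state_dict(best_state)
    return Checkpoint(
        state=best_state, modalities=tuple(modalities),
        use_contrastive=use_contrastive, train_config=train_config,
        encoder_config=encoder_config,
        contrastive_config=contrastive_config, bounds=bounds,
        feature_names=tuple(feature_names), best_epoch=best_epoch,
        history=history)


def _rebuild_model(ckpt: Checkpoint) -> LNMModel:
    model = LNMModel(ckpt.modalities, ckpt.use_contrastive,
                     len(ckpt.feature_names), ckpt.encoder_config,
                     ckpt.contrastive_config, np.random.default_rng(0))
    model.load_state_dict(ckpt.state)
    model.eval()
    return model


def predict_scores(ckpt: Checkpoint, records) -> np.ndarray:
    """Positive-class probabilities for `records` under the checkpoint."""
    return _predict_proba(_rebuild_model(ckpt), records, ckpt.bounds,
                          ckpt.feature_names)


def evaluate_checkpoint(ckpt: Checkpoint, records) -> dict[str, float]:
    """ACC/SE/SP/AUC (all as percentages) on `records`."""
    labels = np.array([r.label for r in records])
    probs = predict_scores(ckpt, records)
    counts = confusion_from_pairs(labels, _hard_predictions(probs))
    out = confusion_metrics(counts)
    out["AUC"] = 100.0 * roc_auc(probs, labels).auc
    return out


# ------------------------------------------------------------- persistence

def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> Path:
    """Single-file .npz checkpoint: weights + JSON metadata."""
    path = Path(path)
    meta = {
        "modalities": list(ckpt.modalities),
        "use_contrastive": ckpt.use_contrastive,
        "train_config": dataclasses.asdict(ckpt.train_config),
        "encoder_config": dataclasses.asdict(ckpt.encoder_config),
        "contrastive_config": dataclasses.asdict(ckpt.contrastive_config),
        "feature_names": list(ckpt.feature_names),
        "best_epoch": ckpt.best_epoch,
        "history": ckpt.history,
        "has_bounds": ckpt.bounds is not None,
    }
    arrays = {f"state/{k}": v for k, v in ckpt.state.items()}
    if ckpt.bounds is not None:
        arrays["bounds"] = ckpt.bounds
    np.savez(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> Checkpoint:
    data = np.load(Path(path))
    meta = json.loads(bytes(data["meta"]).decode())
    enc_meta = dict(meta["encoder_config"])
    enc_meta["crop_area_range"] = tuple(enc_meta["crop_area_range"])
    return Checkpoint(
        state={k.removeprefix("state/"): data[k] for k in data.files
               if k.startswith("state/")},
        modalities=tuple(meta["modalities"]),
        use_contrastive=bool(meta["use_contrastive"]),
        train_config=TrainConfig(**meta["train_config"]),
        encoder_config=EncoderConfig(**enc_meta),
        contrastive_config=ContrastiveConfig(**meta["contrastive_config"]),
        bounds=data["bounds"] if meta["has_bounds"] else None,
        feature_names=tuple(meta["feature_names"]),
        best_epoch=int(meta["best_epoch"]),
        history=meta["history"])
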