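"""End-to-end orchestration: simulate -> split -> train -> evaluate ->
baseline statistics, driven by a single run configuration.

A single global seed fans out to stage-specific sub-seeds (a stable
hash of the stage name mixed with the seed), so e.g. re-seeding the
training stage never silently changes the generated cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .clinical import DEFAULT_FEATURES
from .cohort import SyntheticParams, generate_cohort, write_cohort
from .contrastive import ContrastiveConfig
from .encoders import EncoderConfig
from .evaluation import roc_auc
from .stats import baseline_table
from .training import (TrainConfig, evaluate_checkpoint, predict_scores,
                       save_checkpoint, split_cohort, train)

__all__ = ["RunConfig", "ConfigError", "derive_seed", "run_pipeline",
           "default_config"]

_REQUIRED_BLOCKS = ("cohort", "encoder", "contrastive", "train", "output_dir")


class ConfigError(ValueError):
    """A run configuration block is missing or invalid."""


@dataclasses.dataclass
class RunConfig:
    cohort: SyntheticParams
    encoder: EncoderConfig
    contrastive: ContrastiveConfig
    train: TrainConfig
    output_dir: Path
    seed: int = 0
    modalities: tuple[str, ...] = ("ct", "us", "clinical")
    use_contrastive: bool = True
    stratified_split: bool = True
    feature_names: tuple[str, ...] = DEFAULT_FEATURES

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        for block in _REQUIRED_BLOCKS:
            if block not in raw:
                raise ConfigError(f"configuration is missing the "
                                  f"{block!r} block")
        seed = int(raw.get("seed", 0))
        enc = dict(raw["encoder"])
        if "crop_area_range" in enc:
            enc["crop_area_range"] = tuple(enc["crop_area_range"])
        cohort_block = dict(raw["cohort"])
        cohort_block.setdefault("seed", derive_seed(seed, "cohort"))
        enc.setdefault("seed", derive_seed(seed, "encoder"))
        train_block = dict(raw["train"])
        train_block.setdefault("seed", derive_seed(seed, "train"))
        try:
            return cls(
                cohort=SyntheticParams(**cohort_block),
                encoder=EncoderConfig(**enc),
                contrastive=ContrastiveConfig(**raw["contrastive"]),
                train=TrainConfig(**train_block),
                output_dir=Path(raw["output_dir"]),
                seed=seed,
                modalities=tuple(raw.get("modalities",
                                         ("ct", "us", "clinical"))),
                use_contrastive=bool(raw.get("use_contrastive", True)),
                stratified_split=bool(raw.get("stratified_split", True)),
                feature_names=tuple(raw.get("feature_names",
                                            DEFAULT_FEATURES)),
            )
        except TypeError as exc:
            raise ConfigError(f"invalid configuration field: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["encoder"]["crop_area_range"] = list(
            self.encoder.crop_area_range)
        return d


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def default_config(output_dir: str | Path, seed: int = 0,
                   test_scale: bool = True) -> RunConfig:
    """A complete run configuration; the test-scale variant uses 64-px
    images with the reduced-depth backbone so a run finishes on one CPU
    in minutes."""
    raw = {
        "seed": seed,
        "cohort": {"n_patients": 127, "n_positive": 16,
                   "image_size": 64 if test_scale else 224,
                   "effect_ct": 1.0, "effect_us": 1.0, "effect_clin": 1.0,
                   "noise_sd": 0.10},
        "encoder": {"image_input_side": 64 if test_scale else 224,
                    "backbone": "reduced" if test_scale else "resnet18"},
        "contrastive": {},
        "train": {"epochs": 10 if test_scale else 30},
        "output_dir": str(output_dir),
    }
    return RunConfig.from_dict(raw)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, writing all artifacts under the output directory:
    cohort manifest, checkpoint, per-epoch JSON-lines log, metrics report,
    baseline table, and the fully resolved configuration."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    try:
        cohort = generate_cohort(config.cohort)
        manifest = write_cohort(cohort, out / "cohort", overwrite=True)
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc
    try:
        split = split_cohort(cohort, seed=derive_seed(config.seed, "split"),
                             stratified=config.stratified_split)
        with open(out / "split.json", "w") as fh:
            json.dump(dataclasses.asdict(split), fh, indent=2)
        ckpt = train(cohort, split, config.train, config.encoder,
                     config.contrastive, modalities=config.modalities,
                     use_contrastive=config.use_contrastive,
                     feature_names=config.feature_names,
                     log_file=out / "train_log.jsonl")
        save_checkpoint(ckpt, out / "checkpoint.npz")
    except Exception as exc:
        raise RuntimeError(f"train stage failed: {exc}") from exc
    try:
        test_records = [cohort.records[i] for i in split.test_ids]
        metrics = evaluate_checkpoint(ckpt, test_records)
        scores = predict_scores(ckpt, test_records)
        labels = [r.label for r in test_records]
        curve = roc_auc(scores, labels)
        report = {
            "test_metrics": metrics,
            "best_epoch": ckpt.best_epoch,
            "n_test": len(test_records),
            "roc": {"fpr": curve.fpr.tolist(), "tpr": curve.tpr.tolist()},
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"evaluate stage failed: {exc}") from exc
    try:
        table = baseline_table(cohort.clinical_frame())
        table.to_csv(out / "baseline_table.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stats stage failed: {exc}") from exc
    return out
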