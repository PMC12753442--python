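"""Synthetic multi-modal cohort generation and on-disk round-tripping.

Emulates the statistical structure of a retrospective cervical-cancer
cohort used for lymph-node-metastasis (LNM) prediction: a strongly
imbalanced binary label (default 16 positive of 127), one CT-like and
one ultrasound-like grayscale image per patient, and nine laboratory /
clinical indicators drawn from truncated normals centred in their
clinical reference ranges.

Generative recipe (documented in docs/methods.md): each image is a
smooth low-frequency background plus pixel noise; positive patients
additionally receive a Gaussian blob of class-signal amplitude at a
random location, independently per modality.  Positive patients'
clinical values are shifted by ``effect_clin`` standardized units in the
clinically expected direction (higher SCC-Ag, neutrophils, platelets;
lower lymphocytes, albumin).  FIGO stage is an ordinal drawn from
label-dependent probabilities whose association strength scales with
``effect_clin``.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SyntheticParams", "PatientRecord", "Cohort",
    "generate_cohort", "write_cohort", "read_cohort",
    "CLINICAL_FIELDS",
]

#: (name, negative-class mean, sd, lower clip, upper clip, shift direction)
#: Means/sds sit inside the assay reference ranges: SCC-Ag threshold
#: 1.8 ng/mL; CA125 < 35 U/mL; CA19-9 < 39 U/mL; neutrophils 1.8-6.3,
#: lymphocytes 1.1-3.2, platelets 125-350 (x10^9/L); albumin 40-55 g/L.
CLINICAL_FIELDS: list[tuple[str, float, float, float, float, int]] = [
    ("age",          54.0, 10.0, 25.0,  88.0,  0),
    ("scc_ag",        2.0,  1.0,  0.05, 30.0, +1),
    ("ca125",        20.0,  8.0,  1.0, 500.0, +1),
    ("ca19_9",       18.0,  8.0,  1.0, 500.0, +1),
    ("neutrophils",   4.0,  1.1,  0.5,  20.0, +1),
    ("lymphocytes",   2.0,  0.5,  0.3,   8.0, -1),
    ("platelets",   240.0, 55.0, 20.0, 900.0, +1),
    ("albumin",      45.0,  3.5, 22.0,  60.0, -1),
]

# FIGO stage probabilities: label-independent baseline vs the strongly
# associated pattern reached at effect_clin >= 3
_STAGE_BASE = np.array([0.60, 0.35, 0.04, 0.01])
_STAGE_POSITIVE = np.array([0.05, 0.15, 0.45, 0.35])

_BLOB_AMPLITUDE_PER_EFFECT = 0.12   # image intensity units per unit effect
_BACKGROUND_SD = 0.10               # low-frequency background amplitude
_BACKGROUND_GRID = 4                # coarse grid side for the background


class ValidationError(ValueError):
    """Raised when synthetic-cohort parameters violate their invariants."""


@dataclasses.dataclass(frozen=True)
class SyntheticParams:
    """Generation knobs; identical params + seed give identical cohorts."""

    seed: int = 0
    n_patients: int = 127
    n_positive: int = 16
    image_size: int = 64
    effect_ct: float = 1.0
    effect_us: float = 1.0
    effect_clin: float = 1.0
    noise_sd: float = 0.10

    def validate(self) -> None:
        for name in ("effect_ct", "effect_us", "effect_clin", "noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v!r}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_positive > self.n_patients:
            raise ValidationError(
                f"n_positive ({self.n_positive}) exceeds n_patients "
                f"({self.n_patients})")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")


@dataclasses.dataclass
class PatientRecord:
    """One patient: paired CT/US images, raw clinical values, LNM label."""

    patient_id: str
    ct_image: np.ndarray          # (H, W) float in [0, 1]
    us_image: np.ndarray          # (H, W) float in [0, 1]
    clinical_raw: dict[str, float]
    label: int                    # 1 = lymph-node metastasis


@dataclasses.dataclass
class Cohort:
    records: list[PatientRecord]
    provenance: SyntheticParams | str | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def clinical_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": r.patient_id, **r.clinical_raw,
                 "label": r.label} for r in self.records]
        return pd.DataFrame(rows)


def _smooth_background(rng: np.random.Generator, size: int) -> np.ndarray:
    """Bilinear upsampling of a coarse random grid: low-frequency field."""
    coarse = rng.normal(0.0, _BACKGROUND_SD,
                        (_BACKGROUND_GRID, _BACKGROUND_GRID))
    xs = np.linspace(0, _BACKGROUND_GRID - 1, size)
    i0 = np.clip(xs.astype(int), 0, _BACKGROUND_GRID - 2)
    frac = xs - i0
    rows = (coarse[i0, :] * (1 - frac)[:, None]
            + coarse[i0 + 1, :] * frac[:, None])
    cols = (rows[:, i0] * (1 - frac)[None, :]
            + rows[:, i0 + 1] * frac[None, :])
    return cols


def _gaussian_blob(rng: np.random.Generator, size: int,
                   amplitude: float) -> np.ndarray:
    sigma = size / 6.0
    cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
    yy, xx = np.mgrid[0:size, 0:size]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                              / (2 * sigma ** 2))


def _synth_image(rng: np.random.Generator, size: int, positive: bool,
                 effect: float, noise_sd: float) -> np.ndarray:
    img = 0.45 + _smooth_background(rng, size)
    if positive and effect > 0:
        img += _gaussian_blob(rng, size, _BLOB_AMPLITUDE_PER_EFFECT * effect)
    img += rng.normal(0.0, noise_sd, (size, size))
    return np.clip(img, 0.0, 1.0)


def _synth_clinical(rng: np.random.Generator, positive: bool,
                    effect: float) -> dict[str, float]:
    values: dict[str, float] = {}
    for name, mean, sd, lo, hi, direction in CLINICAL_FIELDS:
        mu = mean + (effect * direction * sd if positive else 0.0)
        values[name] = float(np.clip(rng.normal(mu, sd), lo, hi))
    w = min(effect / 3.0, 1.0) if positive else 0.0
    probs = (1 - w) * _STAGE_BASE + w * _STAGE_POSITIVE
    values["figo_stage"] = int(rng.choice([1, 2, 3, 4], p=probs))
    return values


def generate_cohort(params: SyntheticParams) -> Cohort:
    """Generate a deterministic synthetic cohort from `params`."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    labels = np.zeros(params.n_patients, dtype=int)
    labels[:params.n_positive] = 1
    rng.shuffle(labels)
    width = max(4, len(str(params.n_patients)))
    records = []
    for i, label in enumerate(labels):
        positive = bool(label)
        records.append(PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            ct_image=_synth_image(rng, params.image_size, positive,
                                  params.effect_ct, params.noise_sd),
            us_image=_synth_image(rng, params.image_size, positive,
                                  params.effect_us, params.noise_sd),
            clinical_raw=_synth_clinical(rng, positive, params.effect_clin),
            label=int(label),
        ))
    return Cohort(records=records, provenance=params)


# --------------------------------------------------------------------- I/O

def _write_image(img: np.ndarray, path: Path) -> None:
    arr = np.round(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    if path.suffix.lower() == ".png":
        Image.fromarray(arr, mode="L").save(path)
    elif path.suffix.lower() in (".dcm", ".dicom"):
        _write_dicom(arr, path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def _write_dicom(arr: np.ndarray, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import (ExplicitVRLittleEndian, SecondaryCaptureImageStorage,
                             generate_uid)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def load_image(path: Path | str) -> np.ndarray:
    """Load a grayscale PNG or DICOM file to a float array in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        denom = float(2 ** int(ds.BitsStored) - 1)
    else:
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
        denom = 255.0
    return arr / denom


def write_cohort(cohort: Cohort, directory: Path | str,
                 image_format: str = "png", overwrite: bool = False) -> Path:
    """Write images, a clinical CSV and a manifest CSV; return the manifest.

    Layout: ``manifest.csv`` (patient_id, ct_path, us_path, label),
    ``clinical.csv`` (patient_id + raw indicators + figo_stage),
    ``images/<id>_{ct,us}.<ext>``.  Refuses to clobber an existing
    manifest unless ``overwrite``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace")
    ext = {"png": "png", "dicom": "dcm", "dcm": "dcm"}.get(image_format)
    if ext is None:
        raise ValueError(f"unsupported image_format: {image_format!r}")
    img_dir = directory / "images"
    img_dir.mkdir(exist_ok=True)
    rows, clin_rows = [], []
    for rec in cohort.records:
        ct_rel = f"images/{rec.patient_id}_ct.{ext}"
        us_rel = f"images/{rec.patient_id}_us.{ext}"
        _write_image(rec.ct_image, directory / ct_rel)
        _write_image(rec.us_image, directory / us_rel)
        rows.append({"patient_id": rec.patient_id, "ct_path": ct_rel,
                     "us_path": us_rel, "label": rec.label})
        clin_rows.append({"patient_id": rec.patient_id, **rec.clinical_raw})
    cols = ["patient_id", "ct_path", "us_path", "label"]
    pd.DataFrame(rows, columns=cols).to_csv(manifest_path, index=False)
    clin_cols = ["patient_id"] + [f[0] for f in CLINICAL_FIELDS] + ["figo_stage"]
    pd.DataFrame(clin_rows, columns=clin_cols).to_csv(
        directory / "clinical.csv", index=False)
    return manifest_path


def read_cohort(manifest: Path | str) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (PNG/DICOM mixable)."""
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    base = manifest.parent
    table = pd.read_csv(manifest)
    for col in ("patient_id", "ct_path", "us_path", "label"):
        if col not in table.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient ids in manifest: "
                         f"{sorted(set(dupes))}")
    clin_path = base / "clinical.csv"
    if not clin_path.exists():
        raise FileNotFoundError(f"clinical table not found: {clin_path}")
    clinical = pd.read_csv(clin_path).set_index("patient_id")
    records = []
    for row in table.itertuples(index=False):
        for rel in (row.ct_path, row.us_path):
            if not (base / rel).exists():
                raise FileNotFoundError(
                    f"image file {rel!r} for patient "
                    f"{row.patient_id!r} is missing")
        if row.patient_id not in clinical.index:
            raise KeyError(f"patient {row.patient_id!r} absent from "
                           "clinical.csv")
        records.append(PatientRecord(
            patient_id=str(row.patient_id),
            ct_image=load_image(base / row.ct_path),
            us_image=load_image(base / row.us_path),
            clinical_raw=clinical.loc[row.patient_id].to_dict(),
            label=int(row.label),
        ))
    return Cohort(records=records, provenance=str(manifest))
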