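"""Clinical-indicator preprocessing.

Derived inflammation/nutrition indices (NLR, PLR, SII, PNI), tumor-marker
threshold flags, and the train-split min-max normalization that maps the
clinical feature vector into [0, 1] before the clinical encoder.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "MarkerThresholds", "ClinicalVector", "DEFAULT_FEATURES",
    "derived_indices", "binarize_markers",
    "fit_normalizer", "apply_normalizer", "clinical_matrix",
]


@dataclasses.dataclass(frozen=True)
class MarkerThresholds:
    """Clinical elevation thresholds for the serum tumor markers."""

    scc_ag: float = 1.8     # ng/mL
    ca125: float = 35.0     # U/mL
    ca19_9: float = 39.0    # U/mL


#: Feature order fed to the clinical encoder.  Raw indicators plus the
#: four derived indices; FIGO stage excluded by default (the stage-label
#: association is near-deterministic, which would trivialize the task).
DEFAULT_FEATURES: tuple[str, ...] = (
    "age", "scc_ag", "ca125", "ca19_9", "neutrophils", "lymphocytes",
    "platelets", "albumin", "nlr", "plr", "sii", "pni",
)


@dataclasses.dataclass
class ClinicalVector:
    values: np.ndarray                 # normalized, every entry in [0, 1]
    feature_names: tuple[str, ...]
    normalization_bounds: np.ndarray   # (F, 2) of (min, max)


def derived_indices(clinical_raw: dict, pni_multiplier: float = 5.0) -> dict:
    """Inflammation / nutrition indices from the complete blood count.

    NLR = neutrophils / lymphocytes; PLR = platelets / lymphocytes;
    SII = platelets x neutrophils / lymphocytes (all counts x10^9/L);
    PNI = albumin (g/L) + `pni_multiplier` x lymphocytes.  The
    conventional multiplier is 5, which is also what reproduces typical
    published PNI magnitudes (about 50 for albumin about 42); pass 1 for
    the plain albumin-plus-lymphocytes form.
    """
    for field in ("neutrophils", "lymphocytes", "platelets", "albumin"):
        if field not in clinical_raw:
            raise KeyError(f"missing clinical field {field!r}")
    lymph = float(clinical_raw["lymphocytes"])
    if lymph <= 0:
        raise ValueError(f"lymphocyte count must be > 0, got {lymph}")
    neut = float(clinical_raw["neutrophils"])
    plt = float(clinical_raw["platelets"])
    alb = float(clinical_raw["albumin"])
    return {
        "nlr": neut / lymph,
        "plr": plt / lymph,
        "sii": plt * neut / lymph,
        "pni": alb + pni_multiplier * lymph,
    }


def binarize_markers(clinical_raw: dict,
                     thresholds: MarkerThresholds = MarkerThresholds()) -> dict:
    """Elevated-marker flags: value >= threshold counts as elevated
    (the lower bound is inclusive)."""
    flags = {}
    for field, cut in (("scc_ag", thresholds.scc_ag),
                       ("ca125", thresholds.ca125),
                       ("ca19_9", thresholds.ca19_9)):
        if field not in clinical_raw or clinical_raw[field] is None:
            raise KeyError(f"missing marker field {field!r}")
        flags[f"{field}_elevated"] = bool(float(clinical_raw[field]) >= cut)
    return flags


def clinical_matrix(records, feature_names: tuple[str, ...] = DEFAULT_FEATURES,
                    pni_multiplier: float = 5.0) -> np.ndarray:
    """Raw (n, F) feature matrix in `feature_names` order, computing the
    derived indices on the fly."""
    rows = []
    for rec in records:
        raw = dict(rec.clinical_raw)
        raw.update(derived_indices(raw, pni_multiplier))
        try:
            rows.append([float(raw[f]) for f in feature_names])
        except KeyError as exc:
            raise KeyError(f"patient {rec.patient_id!r} is missing "
                           f"clinical field {exc.args[0]!r}") from None
    return np.asarray(rows, dtype=np.float64)


def fit_normalizer(train_matrix: np.ndarray) -> np.ndarray:
    """Per-feature (min, max) bounds from the *training split only*."""
    train_matrix = np.asarray(train_matrix, dtype=np.float64)
    if train_matrix.ndim != 2 or train_matrix.shape[0] == 0:
        raise ValueError("training matrix must be non-empty and 2-D")
    if not np.isfinite(train_matrix).all():
        raise ValueError("training matrix contains non-finite values")
    return np.stack([train_matrix.min(axis=0),
                     train_matrix.max(axis=0)], axis=1)


def apply_normalizer(matrix: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Min-max scale into [0, 1], clipping held-out values that fall
    outside the training range; a constant feature maps to 0."""
    matrix = np.asarray(matrix, dtype=np.float64)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (matrix - lo) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    return np.clip(scaled, 0.0, 1.0)
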