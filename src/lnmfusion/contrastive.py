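"""Contrastive alignment of the three modality representations.

Projection heads map each 512-d representation into a 128-d contrastive
space; per-patient cross-modality pairs are positives and cross-patient
pairs negatives under an InfoNCE loss on cosine similarity with
temperature tau (default 1).  The combined contrastive objective is the
mean of the three ordered pair losses (ct->clin, us->clin, ct->us).

Two denominator conventions are supported.  The default ("literal")
excludes the positive pair from the denominator, i.e. for anchor i

    L_i = -log [ exp(s_ii / tau) / sum_{j != i} exp(s_ij / tau) ]

which can therefore be negative; the conventional InfoNCE form that
includes the positive is available via
``include_positive_in_denominator=True``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Linear, Module, Tensor

__all__ = [
    "ContrastiveConfig", "ProjectionBundle", "ProjectionHead",
    "cosine_similarity", "info_nce", "combined_contrastive",
    "PairLoss", "CombinedLoss",
]

PROJECTION_DIM = 128
_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class ContrastiveConfig:
    temperature: float = 1.0
    projection_dim: int = PROJECTION_DIM
    include_positive_in_denominator: bool = False
    symmetrize: bool = False

    def validate(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, "
                             f"got {self.temperature}")


@dataclasses.dataclass
class ProjectionBundle:
    """Aligned (n, 128) contrastive embeddings, one matrix per modality;
    row i of every matrix belongs to the same patient."""

    z_ct: Tensor | None = None
    z_us: Tensor | None = None
    z_clin: Tensor | None = None

    def present(self) -> dict[str, Tensor]:
        return {k: v for k, v in (("ct", self.z_ct), ("us", self.z_us),
                                  ("clinical", self.z_clin))
                if v is not None}


@dataclasses.dataclass
class PairLoss:
    per_anchor: Tensor      # length-n vector of anchor losses
    mean: Tensor            # scalar


@dataclasses.dataclass
class CombinedLoss:
    pair_losses: dict[str, PairLoss]    # keys like "ct-clinical"
    mean: Tensor


class ProjectionHead(Module):
    """Two-layer perceptron 512 -> 256 -> 128 with a rectifier between."""

    def __init__(self, feature_dim: int, rng: np.random.Generator,
                 projection_dim: int = PROJECTION_DIM, hidden: int = 256):
        super().__init__()
        self.fc1 = Linear(feature_dim, hidden, rng)
        self.fc2 = Linear(hidden, projection_dim, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).relu())


def cosine_similarity(za: np.ndarray, zb: np.ndarray) -> float:
    """Cosine of the angle between two vectors; zero-norm input raises."""
    za = np.asarray(za, dtype=np.float64).ravel()
    zb = np.asarray(zb, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(za), np.linalg.norm(zb)
    if na <= _EPS or nb <= _EPS:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(za @ zb / (na * nb), -1.0, 1.0))


def _as_tensor(z) -> Tensor:
    return z if isinstance(z, Tensor) else Tensor(np.asarray(z))


def _normalize_rows(z: Tensor) -> Tensor:
    norms_sq = (z * z).sum(axis=1, keepdims=True)
    if np.any(norms_sq.data <= _EPS):
        raise ValueError("zero-norm embedding row: cosine similarity "
                         "undefined")
    return z * (norms_sq ** -0.5)


def _one_direction(za: Tensor, zb: Tensor,
                   config: ContrastiveConfig) -> Tensor:
    n = za.data.shape[0]
    sims = _normalize_rows(za) @ _normalize_rows(zb).T    # (n, n)
    logits = sims * (1.0 / config.temperature)
    if config.include_positive_in_denominator:
        mask = np.ones((n, n), dtype=np.float32)
    else:
        mask = 1.0 - np.eye(n, dtype=np.float32)
    # max-subtraction over the allowed denominator terms, detached
    masked_vals = np.where(mask > 0, logits.data, -np.inf)
    m = Tensor(masked_vals.max(axis=1, keepdims=True))
    denom = (((logits - m).exp() * Tensor(mask)).sum(axis=1, keepdims=True))
    idx = np.arange(n)
    diag = logits[idx, idx]
    lse = (m + denom.log()).reshape(n)
    return lse - diag


def info_nce(za, zb, config: ContrastiveConfig = ContrastiveConfig()) -> PairLoss:
    """Per-anchor InfoNCE losses of `za` anchors against `zb`, and their
    mean.  Requires n >= 2 so the denominator has at least one negative."""
    config.validate()
    za, zb = _as_tensor(za), _as_tensor(zb)
    if za.data.ndim != 2 or zb.data.ndim != 2:
        raise ValueError("embeddings must be 2-D (n, d) matrices")
    if za.data.shape != zb.data.shape:
        raise ValueError(f"embedding shape mismatch: "
                         f"{za.data.shape} vs {zb.data.shape}")
    if za.data.shape[0] < 2:
        raise ValueError("InfoNCE needs a batch of at least 2 patients")
    per_anchor = _one_direction(za, zb, config)
    if config.symmetrize:
        per_anchor = (per_anchor + _one_direction(zb, za, config)) * 0.5
    return PairLoss(per_anchor=per_anchor, mean=per_anchor.mean())


_PAIR_ORDER = (("ct", "clinical"), ("us", "clinical"), ("ct", "us"))


def combined_contrastive(proj: ProjectionBundle,
                         config: ContrastiveConfig = ContrastiveConfig()
                         ) -> CombinedLoss:
    """Mean of the ordered pair losses over the modalities present in
    `proj` (all three: ct->clin, us->clin, ct->us)."""
    present = proj.present()
    if len(present) < 2:
        raise ValueError("combined contrastive loss needs at least two "
                         "modalities")
    rows = {k: v.data.shape[0] for k, v in present.items()}
    if len(set(rows.values())) != 1:
        raise ValueError(f"row-count mismatch across modalities: {rows}")
    pair_losses: dict[str, PairLoss] = {}
    terms = []
    for a, b in _PAIR_ORDER:
        if a in present and b in present:
            loss = info_nce(present[a], present[b], config)
            pair_losses[f"{a}-{b}"] = loss
            terms.append(loss.mean)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return CombinedLoss(pair_losses=pair_losses,
                        mean=total * (1.0 / len(terms)))
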