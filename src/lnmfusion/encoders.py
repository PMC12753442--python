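"""Per-modality encoders and the random-crop-resize augmentation.

Each modality is mapped to a D = 512 dimensional representation:
images through a residual convolutional backbone truncated before any
classification layer, the clinical vector through a two-layer
perceptron (F -> 256 -> 512 with a rectifier between the layers and no
nonlinearity after the second, since the features feed both the
projection heads and the fusion classifier).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Linear, Module, ResNetBackbone, Tensor

__all__ = [
    "EncoderConfig", "FeatureBundle",
    "random_crop_resize", "ImageEncoder", "ClinicalEncoder",
]

FEATURE_DIM = 512


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    feature_dim: int = FEATURE_DIM
    clinical_hidden: int = 256
    image_input_side: int = 224
    crop_area_range: tuple[float, float] = (0.7, 1.0)
    backbone: str = "reduced"          # "reduced" (CPU scale) or "resnet18"
    pretrained_init: bool = False
    pretrained_weights: str | None = None   # .npz state dict when pretrained
    share_image_backbone: bool = False
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.crop_area_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"crop_area_range must satisfy "
                             f"0 < low <= high <= 1, got {(lo, hi)}")
        if self.backbone not in ("reduced", "resnet18"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.image_input_side < 8:
            raise ValueError("image_input_side must be >= 8")


@dataclasses.dataclass
class FeatureBundle:
    """The triple of 512-d modality representations for one batch."""

    h_ct: Tensor | None = None
    h_us: Tensor | None = None
    h_clin: Tensor | None = None


def _resize_bilinear(img: np.ndarray, side: int) -> np.ndarray:
    """Deterministic bilinear resize of a 2-D array to (side, side)."""
    h, w = img.shape
    if (h, w) == (side, side):
        return img.astype(np.float64, copy=True)

    def _axis_coords(n_in, n_out):
        # align-corners-free mapping, matching common image resamplers
        c = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        return np.clip(c, 0, n_in - 1)

    ys, xs = _axis_coords(h, side), _axis_coords(w, side)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    top = img[np.ix_(y0, x0)] * (1 - wx) + img[np.ix_(y0, x1)] * wx
    bot = img[np.ix_(y1, x0)] * (1 - wx) + img[np.ix_(y1, x1)] * wx
    return top * (1 - wy) + bot * wy


def random_crop_resize(image: np.ndarray, config: EncoderConfig,
                       rng: np.random.Generator | None = None,
                       training: bool = True) -> np.ndarray:
    """Random square crop (area fraction uniform over the configured
    range) resized to ``image_input_side``.

    In evaluation mode (``training=False``) the crop is the full image
    (area fraction 1.0, centred), so evaluation is deterministic.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 8:
        raise ValueError(f"image must be 2-D and at least 8x8, "
                         f"got shape {image.shape}")
    h, w = image.shape
    if training:
        if rng is None:
            raise ValueError("training-mode cropping requires an rng")
        lo, hi = config.crop_area_range
        frac = rng.uniform(lo, hi)
        side = max(1, int(round(np.sqrt(frac * h * w))))
        side = min(side, h, w)
        top = rng.integers(0, h - side + 1)
        left = rng.integers(0, w - side + 1)
    else:
        side = min(h, w)
        top = (h - side) // 2
        left = (w - side) // 2
    crop = image[top:top + side, left:left + side]
    return _resize_bilinear(crop, config.image_input_side)


class ImageEncoder(Module):
    """Residual CNN backbone -> D = 512 feature vector per image.

    The 18-layer topology emits 512 channels natively; the reduced
    backbone ends at 32 channels and is followed by an affine widening
    to 512 so the dimension contract is identical in both modes.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.backbone = ResNetBackbone(rng,
                                       depth18=(config.backbone == "resnet18"))
        if self.backbone.out_channels != config.feature_dim:
            self.widen = Linear(self.backbone.out_channels,
                                config.feature_dim, rng)
        else:
            self.widen = None
        if config.pretrained_init:
            self._load_pretrained(config.pretrained_weights)

    def _load_pretrained(self, path: str | None) -> None:
        if path is None:
            raise ValueError(
                "pretrained_init=True requires pretrained_weights to point "
                "at an .npz state dict (no checkpoint is bundled)")
        state = dict(np.load(path))
        self.backbone.load_state_dict(
            {k.removeprefix("backbone."): v for k, v in state.items()
             if k.startswith("backbone.")})

    def forward(self, images: np.ndarray | Tensor) -> Tensor:
        arr = images.data if isinstance(images, Tensor) else np.asarray(images)
        if arr.ndim != 3:
            raise ValueError(f"expected a batch (N, H, W), got {arr.shape}")
        side = self.config.image_input_side
        if arr.shape[1] != side or arr.shape[2] != side:
            raise ValueError(f"images must be {side}x{side} "
                             f"(apply random_crop_resize first), "
                             f"got {arr.shape[1]}x{arr.shape[2]}")
        x = arr[:, None, :, :]
        if self.backbone.in_channels > 1:
            # grayscale replicated across the backbone's input channels
            x = np.repeat(x, self.backbone.in_channels, axis=1)
        feats = self.backbone(Tensor(x))
        if self.widen is not None:
            feats = self.widen(feats)
        return feats


class ClinicalEncoder(Module):
    """Two-layer perceptron F -> clinical_hidden -> D for the normalized
    clinical vector."""

    def __init__(self, n_features: int, config: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.n_features = n_features
        self.fc1 = Linear(n_features, config.clinical_hidden, rng)
        self.fc2 = Linear(config.clinical_hidden, config.feature_dim, rng)

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        if t.data.ndim != 2 or t.data.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) clinical matrix, "
                f"got {t.data.shape}")
        return self.fc2(self.fc1(t).relu())
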