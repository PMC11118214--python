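"""Dataset reading, pre-processing, augmentation and few-shot splitting.

Images are kept as integer-valued 0-255 arrays of shape ``[3, H, W]`` all the
way to the model boundary (normalisation to floats happens at model entry),
so that stored and in-memory representations stay inspectable.  Masks are
integer class maps, background = 0.

Augmentation applies the *same* geometric transform to image and mask:
bilinear resampling for the image, nearest-neighbour for the mask so that
label maps remain integral and no new labels can appear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import transform as sktf

__all__ = [
    "ImageSample", "Manifest", "ManifestEntry", "AugmentConfig",
    "preprocess", "preprocess_mask", "augment_pair", "few_shot_split",
    "replicate_training_set", "load_manifest",
]


@dataclass
class ImageSample:
    """One pre-processed image/mask pair, the unit of training/evaluation."""

    image: np.ndarray            # [3, H, W], integer-valued 0..255
    mask: np.ndarray             # [H, W], integer class indices
    id: str = ""

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError("image must have shape [3, H, W]")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("image and mask must share H, W")


@dataclass(frozen=True)
class ManifestEntry:
    image: str
    mask: str
    split: str = "train"


@dataclass
class Manifest:
    """Index of image/mask pairs; paths are relative to ``root``."""

    entries: list[ManifestEntry]
    n_classes: int
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "Manifest":
        return Manifest([e for e in self.entries if e.split == split],
                        self.n_classes, self.root)

    def load_sample(self, i: int) -> ImageSample:
        e = self.entries[i]
        img = np.asarray(Image.open(self.root / e.image))
        mask = np.asarray(Image.open(self.root / e.mask))
        if img.ndim == 3:
            img = img.transpose(2, 0, 1)
        else:
            img = np.stack([img, img, img])
        return ImageSample(image=img.astype(np.uint8),
                           mask=mask.astype(np.int64),
                           id=Path(e.image).stem)

    def load_all(self) -> list[ImageSample]:
        return [self.load_sample(i) for i in range(len(self))]


def load_manifest(path, n_classes: int) -> Manifest:
    """Read a JSON-lines manifest; every referenced file must exist."""
    path = Path(path)
    root = path.parent
    entries = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            e = ManifestEntry(image=d["image"], mask=d["mask"],
                              split=d.get("split", "train"))
            for p in (e.image, e.mask):
                if not (root / p).exists():
                    raise FileNotFoundError(f"manifest references missing "
                                            f"file: {root / p}")
            entries.append(e)
    return Manifest(entries=entries, n_classes=n_classes, root=root)


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric augmentation settings.

    Defaults follow the training protocol: random central rotations of
    +-10 degrees and replication of the few-shot training set to 512 draws.
    Random shift/scale is available but off by default.
    """

    rotation_deg: float = 10.0
    enable_shift_scale: bool = False
    shift_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    replicate_to: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be >= 0")
        if self.replicate_to < 1:
            raise ValueError("replicate_to must be >= 1")


def preprocess(raw_image: np.ndarray, target_side: int) -> np.ndarray:
    """Convert a 1- or 3-channel image to ``[3, S, S]`` uint8.

    Grayscale inputs are replicated to three identical channels; values are
    clamped to 0..255 integers; spatial resizing is bilinear.  An input
    already at the target size passes through unchanged.
    """
    raw = np.asarray(raw_image)
    if raw.ndim == 2:
        chw = np.stack([raw, raw, raw])
    elif raw.ndim == 3 and raw.shape[2] == 3:
        chw = raw.transpose(2, 0, 1)
    elif raw.ndim == 3 and raw.shape[0] == 3:
        chw = raw
    elif raw.ndim == 3 and raw.shape[2] == 1:
        chw = np.repeat(raw.transpose(2, 0, 1), 3, axis=0)
    else:
        raise ValueError(f"expected 1 or 3 channels, got shape {raw.shape}")
    chw = np.clip(np.rint(chw.astype(np.float64)), 0, 255)
    h, w = chw.shape[1:]
    s = target_side
    if (h, w) != (s, s):
        chw = np.stack([
            sktf.resize(c, (s, s), order=1, preserve_range=True,
                        anti_aliasing=False) for c in chw])
        chw = np.clip(np.rint(chw), 0, 255)
    return chw.astype(np.uint8)


def preprocess_mask(mask: np.ndarray, target_side: int) -> np.ndarray:
    """Companion mask path: nearest-neighbour resize, labels preserved."""
    mask = np.asarray(mask)
    s = target_side
    if mask.shape != (s, s):
        mask = sktf.resize(mask.astype(np.float64), (s, s), order=0,
                           preserve_range=True, anti_aliasing=False)
    return np.rint(mask).astype(np.int64)


def _warp_pair(image: np.ndarray, mask: np.ndarray, tform) -> tuple:
    h, w = mask.shape
    img_out = np.stack([
        sktf.warp(c.astype(np.float64), tform, order=1, cval=0.0,
                  preserve_range=True) for c in image])
    mask_out = sktf.warp(mask.astype(np.float64), tform, order=0, cval=0.0,
                         preserve_range=True)
    return (np.clip(np.rint(img_out), 0, 255).astype(np.uint8),
            np.rint(mask_out).astype(np.int64))


def augment_pair(sample: ImageSample, cfg: AugmentConfig,
                 draw_index: int) -> ImageSample:
    """Apply one random draw of the augmentation to image and mask jointly.

    The draw is a pure function of ``(cfg.seed, draw_index)``.  Rotation is
    about the image centre; out-of-frame pixels are filled with 0 (image) /
    class 0 (mask).
    """
    rng = np.random.default_rng([int(cfg.seed), int(draw_index)])
    angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    if cfg.enable_shift_scale:
        scale = float(rng.uniform(*cfg.scale_range))
        h, w = sample.mask.shape
        shift = rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * (h, w)
    else:
        scale, shift = 1.0, np.zeros(2)

    if angle == 0.0 and scale == 1.0 and not shift.any():
        return ImageSample(image=sample.image.copy(),
                           mask=sample.mask.copy(),
                           id=f"{sample.id}#aug{draw_index}")

    h, w = sample.mask.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])   # (x, y) convention
    t = (sktf.SimilarityTransform(translation=-center)
         + sktf.SimilarityTransform(rotation=np.deg2rad(angle), scale=scale)
         + sktf.SimilarityTransform(translation=center + shift[::-1]))
    img_out, mask_out = _warp_pair(sample.image, sample.mask, t.inverse)
    return ImageSample(image=img_out, mask=mask_out,
                       id=f"{sample.id}#aug{draw_index}")


def few_shot_split(manifest: Manifest, n_train: int,
                   seed: int) -> tuple[Manifest, Manifest]:
    """Deterministically select ``n_train`` entries (seeded shuffle, prefix);
    the remainder is returned untouched."""
    if not (1 <= n_train <= len(manifest)):
        raise ValueError(f"n_train must be in [1, {len(manifest)}], "
                         f"got {n_train}")
    order = np.random.default_rng(int(seed)).permutation(len(manifest))
    take = set(order[:n_train].tolist())
    train = [e for i, e in enumerate(manifest.entries) if i in take]
    rest = [e for i, e in enumerate(manifest.entries) if i not in take]
    return (Manifest(train, manifest.n_classes, manifest.root),
            Manifest(rest, manifest.n_classes, manifest.root))


def replicate_training_set(train: Manifest | list[ImageSample],
                           cfg: AugmentConfig) -> list[ImageSample]:
    """Cycle through the base samples, augmenting with distinct draw indices,
    until ``cfg.replicate_to`` samples exist."""
    base = train.load_all() if isinstance(train, Manifest) else list(train)
    if not base:
        raise ValueError("training set is empty")
    return [augment_pair(base[i % len(base)], cfg, draw_index=i)
            for i in range(cfg.replicate_to)]
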