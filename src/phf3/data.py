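"""Image I/O, preprocessing, augmentation and stratified dataset splitting.

The pipeline follows the usual endoscopy preprocessing recipe: contrast-
limited adaptive histogram equalization (CLAHE) on the lightness channel in
CIELAB (applied deterministically to every image — it enhances vascular
texture and white ulcer heads), resize, then at train time a random crop and
random horizontal/vertical flips (probability 0.3 each), at test time a
center crop; finally per-channel normalization. Defaults use ImageNet
statistics; pure-synthetic runs may supply dataset statistics instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as _skcolor
from skimage import exposure as _skexposure
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "AugmentSpec",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "clahe_enhance",
    "resize_image",
    "normalize_image",
    "train_transform",
    "test_transform",
    "augment_batch",
    "preprocess_eval_batch",
    "stratified_split",
    "kfold_indices",
    "load_manifest",
    "load_images",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class AugmentSpec:
    """Preprocessing/augmentation parameters.

    ``resize``/``crop`` default to the 256→224 full-size pipeline; desk-scale
    64-pixel runs use 72→64 (same ~1.12 resize-to-crop ratio). ``clahe_clip``
    follows the scikit-image convention (fraction of pixels per bin, not the
    OpenCV multiplier); ``clahe_tiles`` is the tile grid per side.
    """

    flip_p: float = 0.3
    resize: int = 256
    crop: int = 224
    clahe_enabled: bool = True
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    mean: tuple = IMAGENET_MEAN
    std: tuple = IMAGENET_STD

    def __post_init__(self):
        if not 0.0 <= self.flip_p <= 1.0:
            raise ValueError(f"flip probability must be in [0,1], got {self.flip_p}")
        if self.crop > self.resize:
            raise ValueError(f"crop {self.crop} exceeds resize {self.resize}")


def clahe_enhance(image: np.ndarray, clip: float = 0.01, tiles: int = 8) -> np.ndarray:
    """CLAHE on the lightness channel of CIELAB; uint8 RGB in and out."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB input, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit input, got dtype {image.dtype}")
    lab = _skcolor.rgb2lab(image)
    lightness = lab[..., 0] / 100.0
    kernel = max(image.shape[0] // tiles, 1), max(image.shape[1] // tiles, 1)
    lab[..., 0] = _skexposure.equalize_adapthist(
        lightness, kernel_size=kernel, clip_limit=clip
    ) * 100.0
    with warnings.catch_warnings():
        # out-of-gamut LAB values are clipped into sRGB; expected after
        # brightening the lightness channel
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        rgb = _skcolor.lab2rgb(lab)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def resize_image(image: np.ndarray, edge: int) -> np.ndarray:
    """Bilinear resize of a uint8 H×W×3 image to edge×edge."""
    return np.asarray(Image.fromarray(image).resize((edge, edge), Image.BILINEAR))


def normalize_image(image: np.ndarray, mean=IMAGENET_MEAN, std=IMAGENET_STD) -> np.ndarray:
    """uint8 H×W×3 → float32 3×H×W, scaled to [0,1] then standardized."""
    x = image.astype(np.float32) / 255.0
    x = (x - np.asarray(mean, dtype=np.float32)) / np.asarray(std, dtype=np.float32)
    return x.transpose(2, 0, 1)


def train_transform(image: np.ndarray, spec: AugmentSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """CLAHE → resize → random crop → random h/v flips → normalize."""
    if spec.clahe_enabled:
        image = clahe_enhance(image, spec.clahe_clip, spec.clahe_tiles)
    image = resize_image(image, spec.resize)
    margin = spec.resize - spec.crop
    oy = int(rng.integers(0, margin + 1))
    ox = int(rng.integers(0, margin + 1))
    image = image[oy : oy + spec.crop, ox : ox + spec.crop]
    if rng.random() < spec.flip_p:
        image = image[:, ::-1]
    if rng.random() < spec.flip_p:
        image = image[::-1, :]
    return normalize_image(np.ascontiguousarray(image), spec.mean, spec.std)


def test_transform(image: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """CLAHE → resize → center crop → normalize; fully deterministic."""
    if spec.clahe_enabled:
        image = clahe_enhance(image, spec.clahe_clip, spec.clahe_tiles)
    image = resize_image(image, spec.resize)
    off = (spec.resize - spec.crop) // 2
    image = image[off : off + spec.crop, off : off + spec.crop]
    return normalize_image(image, spec.mean, spec.std)


# -- batched fast paths used by the training loop ---------------------------
# CLAHE and the resize are deterministic, so the engine applies them once and
# caches the resized uint8 images; per-epoch randomness is crops and flips.

def augment_batch(resized: np.ndarray, spec: AugmentSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Random crop+flip+normalize of cached resized uint8 images [B,R,R,3]."""
    b = resized.shape[0]
    margin = spec.resize - spec.crop
    oys = rng.integers(0, margin + 1, b)
    oxs = rng.integers(0, margin + 1, b)
    hflips = rng.random(b) < spec.flip_p
    vflips = rng.random(b) < spec.flip_p
    out = np.empty((b, 3, spec.crop, spec.crop), dtype=np.float32)
    for i in range(b):
        img = resized[i, oys[i] : oys[i] + spec.crop, oxs[i] : oxs[i] + spec.crop]
        if hflips[i]:
            img = img[:, ::-1]
        if vflips[i]:
            img = img[::-1, :]
        out[i] = normalize_image(np.ascontiguousarray(img), spec.mean, spec.std)
    return out


def preprocess_eval_batch(images: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """test_transform applied image-wise → [B,3,crop,crop] float32."""
    return np.stack([test_transform(img, spec) for img in images])


# -- dataset splitting -------------------------------------------------------

def stratified_split(manifest: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int = 0) -> pd.DataFrame:
    """Per-class train/test split (default 8:2); fills the ``split`` column."""
    if "label" not in manifest.columns:
        raise ValueError("manifest needs a 'label' column")
    idx_train, idx_test = train_test_split(
        np.arange(len(manifest)), test_size=test_fraction,
        stratify=manifest["label"].to_numpy(), random_state=seed,
    )
    out = manifest.copy()
    out["split"] = ""
    out.loc[out.index[idx_train], "split"] = "train"
    out.loc[out.index[idx_test], "split"] = "test"
    return out


def kfold_indices(labels, k: int, seed: int = 0):
    """Stratified k-fold (train_idx, val_idx) pairs; every sample appears in
    exactly one validation fold."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} images, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def load_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"filename", "label"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return manifest


def load_images(manifest: pd.DataFrame, images_dir) -> np.ndarray:
    """Load the manifest's images as a uint8 [N,H,W,3] array."""
    images_dir = Path(images_dir)
    arrays = [
        np.asarray(Image.open(images_dir / fname).convert("RGB"))
        for fname in manifest["filename"]
    ]
    return np.stack(arrays)
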