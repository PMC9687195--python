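"""Interpretability: Grad-CAM heat maps and per-stage feature-map dumps.

Grad-CAM weights each channel of a chosen spatial map by the spatial mean of
the class-score gradient flowing into it, sums, rectifies (ReLU), min-max
normalizes to [0, 1] and bilinearly upsamples to the input size. The default
target layer is the CNN branch's stage-4 output, which gives the crispest
spatial gradients; the Transformer stage-4 map and the channel concatenation
are selectable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib import cm
from PIL import Image
from scipy import ndimage

from .autograd import Tensor
from .fusion import PHF3Net

__all__ = ["gradcam_heatmap", "overlay_heatmap", "dump_feature_maps"]

_LAYERS = ("cnn_stage4", "pvt_stage4", "concat")


def gradcam_heatmap(model: PHF3Net, image: np.ndarray, target_class: int,
                    layer: str = "cnn_stage4") -> np.ndarray:
    """Heat map in [0, 1] with the input's spatial shape.

    ``image`` is one preprocessed [3, H, W] float array (the network input).
    """
    if layer not in _LAYERS:
        raise ValueError(f"layer must name a spatial map, one of {_LAYERS}")
    x = Tensor(np.asarray(image)[None])
    model.eval()
    out = model(x)
    fmap = {"pvt_stage4": model._last_stage4[0],
            "cnn_stage4": model._last_stage4[1],
            "concat": model._last_stage4[2]}[layer]
    model.zero_grad()
    onehot = np.zeros(out.logits_combine.shape, dtype=np.float32)
    onehot[0, target_class] = 1.0
    out.logits_combine.backward(onehot)
    grad = fmap.grad[0]                    # [C, h, w]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * fmap.data[0]).sum(0), 0.0)
    if cam.max() > cam.min():
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    zoom = (image.shape[1] / cam.shape[0], image.shape[2] / cam.shape[1])
    cam = ndimage.zoom(cam, zoom, order=1)
    return np.clip(cam, 0.0, 1.0)


def overlay_heatmap(image_uint8: np.ndarray, heatmap: np.ndarray,
                    alpha: float = 0.45, out_path=None) -> np.ndarray:
    """Blend a [0,1] heat map (jet colormap) over a uint8 RGB image."""
    colored = (cm.jet(heatmap)[..., :3] * 255).astype(np.uint8)
    if colored.shape[:2] != image_uint8.shape[:2]:
        zoom = (image_uint8.shape[0] / heatmap.shape[0],
                image_uint8.shape[1] / heatmap.shape[1], 1)
        colored = np.clip(ndimage.zoom(colored, zoom, order=1), 0, 255).astype(np.uint8)
    blend = ((1 - alpha) * image_uint8 + alpha * colored).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(blend).save(out_path)
    return blend


def _channel_grid(fmap: np.ndarray, max_channels: int = 16) -> np.ndarray:
    """Tile up to ``max_channels`` per-channel maps into one uint8 image."""
    c = min(fmap.shape[0], max_channels)
    cols = int(np.ceil(np.sqrt(c)))
    rows = int(np.ceil(c / cols))
    h, w = fmap.shape[1:]
    grid = np.zeros((rows * h, cols * w), dtype=np.uint8)
    for i in range(c):
        ch = fmap[i]
        rng_ = ch.max() - ch.min()
        norm = (ch - ch.min()) / rng_ if rng_ > 0 else np.zeros_like(ch)
        r, col = divmod(i, cols)
        grid[r * h : (r + 1) * h, col * w : (col + 1) * w] = (norm * 255).astype(np.uint8)
    return grid


def dump_feature_maps(model: PHF3Net, image: np.ndarray, out_dir) -> list[Path]:
    """Save per-stage, per-branch channel grids before and after fusion.

    Stages 1–3 get a pre- and post-fusion grid per branch; stage 4 (no fusion)
    a pre-fusion grid only. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model.eval()
    out = model(Tensor(np.asarray(image)[None]), keep_maps=True)
    written = []
    for stage in range(4):
        for branch, pre_maps, post_maps in (
            ("pvt", out.pvt_maps, out.fused_pvt_maps),
            ("cnn", out.cnn_maps, out.fused_cnn_maps),
        ):
            grids = {"before": pre_maps[stage].data[0]}
            if stage < 3:
                grids["after"] = post_maps[stage].data[0]
            for tag, fmap in grids.items():
                path = out_dir / f"stage{stage + 1}_{branch}_{tag}.png"
                Image.fromarray(_channel_grid(fmap)).save(path)
                written.append(path)
    return written
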