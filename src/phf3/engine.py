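"""Training, evaluation and cross-validation orchestration.

The loop optimizes the three-branch objective
``alpha·L_pvt + beta·L_cnn + gamma·L_combine`` with SGD (momentum 0.9,
weight decay 1e-5), multiplying the learning rate by ``lr_decay`` every
``lr_step`` epochs. CLAHE and the resize are deterministic, so they are
applied once up front and cached; per-epoch randomness (shuffling, crops,
flips) is drawn from a generator re-seeded from ``(seed, epoch)``, which
makes an interrupted-and-resumed run bit-identical to an uninterrupted one
from any epoch boundary.

Checkpoints are ``.npz`` archives holding every model parameter and buffer
(keys ``model/<dotted name>``), the optimizer velocities (``opt/<i>``), the
epoch counter, the config and the metric history as JSON strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor, no_grad
from .cnn import CNNStageConfig
from .config import RunConfig
from .data import augment_batch, clahe_enhance, preprocess_eval_batch, resize_image
from .fusion import PHF3Net
from .losses import label_smoothing_ce, total_loss
from .metrics import MetricsReport
from .nn import SGD
from .pvt import default_pvt_configs, tiny_pvt_configs

__all__ = [
    "build_model",
    "lr_at_epoch",
    "TrainResult",
    "train",
    "evaluate",
    "predict_scores",
    "cross_validate",
    "save_checkpoint",
    "load_checkpoint",
]


def build_model(config: RunConfig, rng=None) -> PHF3Net:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.preset == "paper":
        pvt_cfgs, cnn_cfg = default_pvt_configs(), CNNStageConfig.resnet50()
    elif config.preset == "tiny":
        pvt_cfgs, cnn_cfg = tiny_pvt_configs(), CNNStageConfig.tiny()
    else:
        raise ValueError(f"unknown preset {config.preset!r} (expected 'paper' or 'tiny')")
    return PHF3Net(
        pvt_cfgs, cnn_cfg, num_classes=config.num_classes,
        sop_iterations=config.sop_iterations,
        sop_reduce_channels=config.sop_reduce_channels,
        sop_mode=config.sop_mode, ffm_enabled=config.ffm_enabled, rng=rng,
    )


def lr_at_epoch(config: RunConfig, epoch: int) -> float:
    """Step schedule: lr · decay^(epoch // step); epochs are 0-based."""
    return config.lr * config.lr_decay ** (epoch // config.lr_step)


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), 7919, epoch])


def _check_finite(loss_value: float, model: PHF3Net, epoch: int):
    if np.isfinite(loss_value):
        return
    for name, p in model.named_parameters():
        if not np.all(np.isfinite(p.data)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}; first non-finite parameter: {name}"
            )
    raise RuntimeError(f"non-finite loss at epoch {epoch} (parameters finite)")


def _cache_resized(images: np.ndarray, config: RunConfig) -> np.ndarray:
    """Deterministic preprocessing applied once: CLAHE + resize, kept uint8."""
    spec = config.augment_spec()
    out = np.empty((len(images), spec.resize, spec.resize, 3), dtype=np.uint8)
    for i, img in enumerate(images):
        if spec.clahe_enabled:
            img = clahe_enhance(img, spec.clahe_clip, spec.clahe_tiles)
        out[i] = resize_image(img, spec.resize)
    return out


@dataclass
class TrainResult:
    model: PHF3Net
    config: RunConfig
    history: list = field(default_factory=list)
    best_state: dict | None = None
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")


def train(config: RunConfig, images: np.ndarray, labels: np.ndarray,
          val_images=None, val_labels=None, out_dir=None,
          resume_from=None, verbose: bool = False) -> TrainResult:
    """Train a model on uint8 [N,H,W,3] images with integer labels 0..K-1.

    Logs one record per epoch (lr, mean train loss, training-split accuracy
    measured in eval mode, validation accuracy when a validation split is
    given) to ``history`` and, if ``out_dir`` is set, to ``log.jsonl``; keeps
    the best-by-validation-accuracy state and writes ``best.npz``/``last.npz``.
    """
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty training split")
    spec = config.augment_spec()

    start_epoch = 0
    if resume_from is not None:
        model, opt_state, _, start_epoch, history = load_checkpoint(resume_from)
        result = TrainResult(model, config, history=history)
    else:
        model = build_model(config)
        opt_state = None
        result = TrainResult(model, config)

    optimizer = SGD(model.parameters(), lr=config.lr,
                    momentum=config.momentum, weight_decay=config.weight_decay)
    if opt_state is not None:
        optimizer.load_state_dict(opt_state)

    cached = _cache_resized(images, config)
    val_x = None
    if val_images is not None and len(val_images):
        val_x = preprocess_eval_batch(val_images, spec)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "run.yaml")

    n = len(images)
    for epoch in range(start_epoch, config.epochs):
        optimizer.lr = lr_at_epoch(config, epoch)
        rng = _epoch_rng(config.seed, epoch)
        perm = rng.permutation(n)
        model.train()
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            xb = Tensor(augment_batch(cached[idx], spec, rng))
            yb = labels[idx]
            out = model(xb)
            loss = total_loss(
                label_smoothing_ce(out.logits_pvt, yb, config.label_smoothing),
                label_smoothing_ce(out.logits_cnn, yb, config.label_smoothing),
                label_smoothing_ce(out.logits_combine, yb, config.label_smoothing),
                config.loss_weights,
            )
            optimizer.zero_grad()
            loss.backward()
            _check_finite(loss.item(), model, epoch)
            optimizer.step()
            losses.append(loss.item())

        train_acc = _split_accuracy(model, cached, labels, config)
        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": train_acc,
        }
        if val_x is not None:
            val_acc = _batched_accuracy(model, val_x, np.asarray(val_labels),
                                        config.batch_size)
            record["val_accuracy"] = val_acc
            if not (val_acc <= result.best_val_accuracy):  # NaN-safe
                result.best_val_accuracy = val_acc
                result.best_epoch = epoch
                result.best_state = model.state_dict()
        result.history.append(record)
        if verbose:
            print(json.dumps(record))
        if out_dir is not None:
            with open(out_dir / "log.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
            save_checkpoint(out_dir / "last.npz", model, optimizer,
                            config, epoch + 1, result.history)
            if result.best_epoch == epoch:
                save_checkpoint(out_dir / "best.npz", model, optimizer,
                                config, epoch + 1, result.history)

    if out_dir is not None:
        _history_csv(result.history, out_dir / "history.csv")
    return result


def _history_csv(history, path):
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)


def predict_scores(model: PHF3Net, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Softmax probabilities of the main (combine) head, eval mode, batched."""
    model.eval()
    chunks = []
    with no_grad():  # inference: skip graph construction (memory, speed)
        for lo in range(0, len(x), batch_size):
            logits = model.predict_logits(Tensor(x[lo : lo + batch_size]))
            chunks.append(logits.softmax(axis=-1).data)
    return np.concatenate(chunks)


def _batched_accuracy(model, x, y, batch_size) -> float:
    scores = predict_scores(model, x, batch_size)
    return float((scores.argmax(1) == y).mean())


def _split_accuracy(model, cached_resized, labels, config) -> float:
    """Eval-mode accuracy on a cached-resized split (center crop)."""
    spec = config.augment_spec()
    off = (spec.resize - spec.crop) // 2
    cropped = cached_resized[:, off : off + spec.crop, off : off + spec.crop]
    x = (cropped.astype(np.float32) / 255.0 - np.asarray(spec.mean, np.float32)) \
        / np.asarray(spec.std, np.float32)
    x = x.transpose(0, 3, 1, 2)
    return _batched_accuracy(model, x, labels, config.batch_size)


def evaluate(model: PHF3Net, images: np.ndarray, labels, config: RunConfig,
             batch_size: int | None = None) -> tuple[MetricsReport, np.ndarray]:
    """Deterministic test-time pipeline + combine-head prediction.

    Returns the full metrics report and the [N,K] score matrix.
    """
    spec = config.augment_spec()
    x = preprocess_eval_batch(images, spec)
    scores = predict_scores(model, x, batch_size or config.batch_size)
    report = MetricsReport.from_predictions(
        np.asarray(labels), scores.argmax(1), scores, config.num_classes
    )
    return report, scores


def cross_validate(config: RunConfig, images: np.ndarray, labels,
                   k: int = 5, verbose: bool = False):
    """Stratified k-fold: trains k models, reports per-fold metrics plus the
    unweighted mean accuracy across folds."""
    from .data import kfold_indices

    if k < 2:
        raise ValueError(f"cross-validation needs k >= 2, got {k}")
    labels = np.asarray(labels)
    reports = []
    for fold, (tr, va) in enumerate(kfold_indices(labels, k, config.seed)):
        result = train(config, images[tr], labels[tr],
                       val_images=images[va], val_labels=labels[va],
                       verbose=verbose)
        if result.best_state is not None:
            result.model.load_state_dict(result.best_state)
        report, _ = evaluate(result.model, images[va], labels[va], config)
        reports.append(report)
        if verbose:
            print(f"fold {fold}: accuracy {report.total_accuracy:.4f}")
    accs = [r.total_accuracy for r in reports]
    aggregate = {"fold_accuracies": accs, "mean_accuracy": float(np.mean(accs))}
    return reports, aggregate


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(path, model: PHF3Net, optimizer: SGD | None,
                    config: RunConfig, epoch: int, history: list):
    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        for i, v in enumerate(optimizer._velocity):
            arrays[f"opt/{i}"] = v
    arrays["meta/epoch"] = np.array(epoch)
    arrays["meta/config"] = np.array(json.dumps(config.to_dict()))
    arrays["meta/history"] = np.array(json.dumps(history))
    np.savez_compressed(path, **arrays)


def load_checkpoint(path):
    """Returns (model, optimizer_state_or_None, config, epoch, history)."""
    with np.load(path, allow_pickle=False) as archive:
        arrays = {k: archive[k] for k in archive.files}
    config = RunConfig.from_dict(json.loads(str(arrays.pop("meta/config"))))
    epoch = int(arrays.pop("meta/epoch"))
    history = json.loads(str(arrays.pop("meta/history")))
    model = build_model(config)
    model.load_state_dict(
        {k[len("model/"):]: v for k, v in arrays.items() if k.startswith("model/")}
    )
    vel = [arrays[f"opt/{i}"] for i in range(sum(k.startswith("opt/") for k in arrays))]
    opt_state = None
    if vel:
        opt_state = {"lr": config.lr, "momentum": config.momentum,
                     "weight_decay": config.weight_decay, "velocity": vel}
    return model, opt_state, config, epoch, history
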