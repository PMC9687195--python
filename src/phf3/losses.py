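"""Label-smoothed cross-entropy and the three-branch weighted objective.

The model emits three logit vectors per image (Transformer-branch auxiliary,
CNN-branch auxiliary, and the main combined head); each gets the same
label-smoothed cross-entropy and the total loss is the weighted sum
``alpha·L_pvt + beta·L_cnn + gamma·L_combine`` (default weights 1:1:2).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = ["label_smoothing_ce", "total_loss"]


def label_smoothing_ce(logits, labels, epsilon: float = 0.1, num_classes: int | None = None):
    """Cross-entropy with label smoothing over a batch of logits.

    loss = (1−ε)·mean_n[−log p_{y_n}] + ε·mean_{n,k}[−log p_k]

    i.e. the one-hot target mixed with a uniform distribution with weight ε.
    ``labels`` are 0-based integers in ``[0, K)``. Returns a scalar; a Tensor
    in, gradient-carrying Tensor out, ndarray in, float out.
    """
    arr = not isinstance(logits, Tensor)
    v = as_tensor(logits)
    y = np.asarray(labels)
    if v.ndim != 2:
        raise ValueError(f"expected [batch, classes] logits, got shape {v.shape}")
    n, k = v.shape
    if num_classes is not None and k != num_classes:
        raise ValueError(f"logits have {k} classes, expected {num_classes}")
    if not (0.0 <= epsilon < 1.0):
        raise ValueError(f"smoothing coefficient must be in [0, 1), got {epsilon}")
    if y.shape != (n,):
        raise ValueError(f"labels shape {y.shape} does not match batch size {n}")
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels must lie in [0, {k}), got range [{y.min()}, {y.max()}]")
    if not np.all(np.isfinite(v.data)):
        raise ValueError("non-finite logits passed to the loss")

    logp = v.log_softmax(axis=-1)
    nll = -logp[(np.arange(n), y)].mean()
    uniform = -logp.mean()
    loss = (1.0 - epsilon) * nll + epsilon * uniform
    return loss.item() if arr else loss


def total_loss(loss_pvt, loss_cnn, loss_combine, weights=(1.0, 1.0, 2.0)):
    """Weighted sum of the three branch losses; exactly linear in each term."""
    alpha, beta, gamma = (float(w) for w in weights)
    if min(alpha, beta, gamma) < 0:
        raise ValueError(f"loss weights must be non-negative, got {weights}")
    return alpha * loss_pvt + beta * loss_cnn + gamma * loss_combine
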