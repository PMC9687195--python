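"""Second-order pooling: matrix-square-root-normalized covariance features.

Replaces global average pooling at the network output. Given stage-4 feature
maps reshaped to a channel-by-position matrix ``X`` (C×S), the head computes

1. the position-centered covariance  Σ = X·Ī·Xᵀ  with  Ī = (1/S)(I − (1/S)·11ᵀ),
2. trace pre-normalization  A = Σ / tr(Σ)  so the Newton–Schulz iteration
   converges (all eigenvalues of A lie in [0, 1]),
3. L coupled Newton–Schulz steps  Y_l = ½·Y_{l−1}(3I − Z_{l−1}Y_{l−1}),
   Z_l = ½(3I − Z_{l−1}Y_{l−1})·Z_{l−1}  with Y₀ = A, Z₀ = I, giving Y_L ≈ A^{1/2}
   using matrix multiplications only (no eigendecomposition),
4. post-compensation  Ŷ = √tr(Σ)·Y_L  restoring the data magnitude, so that at
   convergence Ŷ = Σ^{1/2},
5. extraction of the upper-triangular elements (diagonal included, row-major)
   as the feature vector of length C(C+1)/2.

All functions accept either plain ndarrays or autograd Tensors and are
differentiable through the unrolled iteration; batched inputs carry a leading
batch axis on every matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "compute_covariance",
    "pre_normalize",
    "newton_schulz_iterate",
    "post_compensate",
    "extract_upper_triangular",
    "second_order_pool",
    "TRACE_EPS",
]

#: guard added to the trace denominator; constant feature maps (zero covariance)
#: occur with zero-initialized heads and must not produce NaN
TRACE_EPS = 1e-12


def _maybe_unwrap(out: Tensor, was_array: bool):
    return out.data if was_array else out


def compute_covariance(x):
    """Covariance Σ = X·Ī·Xᵀ of a C×S feature matrix (batched: [..., C, S]).

    Equivalent to the 1/S-normalized mean-centered scatter matrix: each channel
    row is centered by its spatial mean before the outer product.
    """
    arr = not isinstance(x, Tensor)
    x = as_tensor(x)
    s = x.shape[-1]
    if s < 1:
        raise ValueError("feature matrix needs at least one spatial position")
    xc = x - x.mean(axis=-1, keepdims=True)
    sigma = (xc @ xc.swapaxes(-1, -2)) * (1.0 / s)
    return _maybe_unwrap(sigma, arr)


def pre_normalize(sigma):
    """Divide Σ by its trace (plus a tiny guard); returns ``(A, trace)``.

    A zero-trace covariance (all-constant features) yields A = 0 with a warning;
    the downstream square root is then exactly zero rather than NaN.
    """
    arr = not isinstance(sigma, Tensor)
    sigma = as_tensor(sigma)
    c = sigma.shape[-1]
    eye = np.eye(c, dtype=sigma.data.dtype)
    trace = (sigma * eye).sum(axis=(-2, -1), keepdims=True)
    if np.any(trace.data <= 0):
        warnings.warn(
            "zero-trace covariance encountered; second-order features will be zero",
            RuntimeWarning,
            stacklevel=2,
        )
    a = sigma / (trace + TRACE_EPS)
    tr_out = trace.data.reshape(trace.shape[:-2]) if arr else trace
    return _maybe_unwrap(a, arr), tr_out


def newton_schulz_iterate(a, n_iter: int):
    """Run ``n_iter`` coupled Newton–Schulz steps; returns Y_L ≈ A^{1/2}.

    Requires tr(A) ≤ 1 for convergence (guaranteed by :func:`pre_normalize`).
    ``n_iter = 0`` returns A unchanged — the "second-order pooling without
    square-root normalization" ablation baseline.
    """
    if n_iter < 0:
        raise ValueError(f"iteration count must be >= 0, got {n_iter}")
    arr = not isinstance(a, Tensor)
    a = as_tensor(a)
    c = a.shape[-1]
    eye = np.eye(c, dtype=a.data.dtype)
    y = a
    z = as_tensor(np.broadcast_to(eye, a.shape).copy())
    for _ in range(n_iter):
        t = 0.5 * (3.0 * eye - z @ y)
        y, z = y @ t, t @ z
    return _maybe_unwrap(y, arr)


def post_compensate(y_l, trace):
    """Multiply by √tr(Σ); for converged iterations the result is Σ^{1/2}."""
    arr = not isinstance(y_l, Tensor)
    y_l = as_tensor(y_l)
    trace = as_tensor(trace)
    t = trace
    if t.ndim < y_l.ndim:  # unbatched trace scalar / batch vector
        t = t.reshape(t.shape + (1,) * (y_l.ndim - t.ndim))
    out = t.sqrt() * y_l
    return _maybe_unwrap(out, arr)


def extract_upper_triangular(y):
    """Row-major upper-triangular elements (diagonal included) of a C×C matrix.

    Output length C(C+1)/2; symmetric reconstruction from the vector is exact.
    The ordering (row-major over i ≤ j) is part of the checkpoint contract.
    """
    arr = not isinstance(y, Tensor)
    y = as_tensor(y)
    c1, c2 = y.shape[-2], y.shape[-1]
    if c1 != c2:
        raise ValueError(f"expected a square matrix, got {c1}x{c2}")
    rows, cols = np.triu_indices(c1)
    idx = (..., rows, cols)
    out = y[idx]
    return _maybe_unwrap(out, arr)


def second_order_pool(feature_map, n_iter: int = 8):
    """Full second-order pooling of a [batch, C, H, W] map → [batch, C(C+1)/2].

    Covariance is computed per image (no pooling across the batch). Default
    ``n_iter=8`` follows the iteration count selected by cross-validation.
    """
    arr = not isinstance(feature_map, Tensor)
    x = as_tensor(feature_map)
    b, c, h, w = x.shape
    xm = x.reshape(b, c, h * w)
    sigma = compute_covariance(xm)
    a, trace = pre_normalize(sigma)
    y = newton_schulz_iterate(a, n_iter)
    yhat = post_compensate(y, trace.reshape(b, 1, 1))
    feats = extract_upper_triangular(yhat)
    return _maybe_unwrap(feats, arr)
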