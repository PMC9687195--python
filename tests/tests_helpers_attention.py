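"""Shared oracle helpers: identity spatial-reduction wiring and textbook
multi-head attention, independent of the library's batched implementation."""

import numpy as np

from phf3 import nn


def identity_sr(sr):
    """Make the spatial-reduction sub-module a no-op (identity conv and
    projection, normalization bypassed)."""
    d = sr.conv.weight.data.shape[0]
    sr.conv.weight.data = np.eye(d, dtype=np.float32).reshape(d, d, 1, 1)
    sr.conv.bias.data = np.zeros(d, dtype=np.float32)
    sr.proj.weight.data = np.eye(d, dtype=np.float32)
    sr.proj.bias.data = np.zeros(d, dtype=np.float32)
    sr.norm = nn.Identity()


def vanilla_attention(tokens, attn, num_heads):
    """Straight-line scaled-dot-product multi-head attention in float64."""
    x = tokens.astype(np.float64)
    q = x @ attn.q.weight.data.T + attn.q.bias.data
    k = x @ attn.k.weight.data.T + attn.k.bias.data
    v = x @ attn.v.weight.data.T + attn.v.bias.data
    d = x.shape[1]
    dh = d // num_heads
    heads = []
    for j in range(num_heads):
        qj = q[:, j * dh : (j + 1) * dh]
        kj = k[:, j * dh : (j + 1) * dh]
        vj = v[:, j * dh : (j + 1) * dh]
        logits = qj @ kj.T / np.sqrt(dh)
        w = np.exp(logits - logits.max(1, keepdims=True))
        w /= w.sum(1, keepdims=True)
        heads.append(w @ vj)
    return np.concatenate(heads, 1) @ attn.out_proj.weight.data.T \
        + attn.out_proj.bias.data
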