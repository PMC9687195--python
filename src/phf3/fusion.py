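"""Feature fusion module and the full dual-branch hybrid network.

After stages 1–3 the two branches exchange information through the FFM:

    M_pvt, M_cnn = Split(G_fuse(Concat(F_pvt, F_cnn)))
    F'_pvt = F_pvt + G_pvt(M_pvt);   F'_cnn = F_cnn + G_cnn(M_cnn)

where G_fuse is a 1×1 convolution over the concatenated channels followed by
ReLU, and G_pvt / G_cnn are per-branch 1×1 convolutions before the residual
add. The fused maps are written back into BOTH branches as the next stage's
input. After stage 4 the branch maps are concatenated channel-wise and sent
through the second-order-pooling head; that head's logits are the model's
main output (inference = argmax over them). Two auxiliary heads — global
average pooling + fully connected on each branch's stage-4 map — exist for
training only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .cnn import CNNBranch, CNNStageConfig
from .pvt import PvTBranch, PvTStageConfig, default_pvt_configs, tiny_pvt_configs
from .sop import second_order_pool

__all__ = ["FFM", "HybridOutputs", "PHF3Net"]


class FFM(nn.Module):
    """Channel-level fusion of one Transformer map and one CNN map."""

    def __init__(self, c_pvt: int, c_cnn: int, *, rng):
        super().__init__()
        self.c_pvt, self.c_cnn = c_pvt, c_cnn
        total = c_pvt + c_cnn
        self.fuse = nn.Conv2d(total, total, 1, rng=rng)
        self.back_pvt = nn.Conv2d(c_pvt, c_pvt, 1, rng=rng)
        self.back_cnn = nn.Conv2d(c_cnn, c_cnn, 1, rng=rng)

    def forward(self, f_pvt: Tensor, f_cnn: Tensor) -> tuple[Tensor, Tensor]:
        if f_pvt.shape[2:] != f_cnn.shape[2:]:
            raise ValueError(
                f"fusion requires equal spatial dims, got {f_pvt.shape} vs {f_cnn.shape}"
            )
        mixed = self.fuse(concat([f_pvt, f_cnn], axis=1)).relu()
        m_pvt = mixed[:, : self.c_pvt]
        m_cnn = mixed[:, self.c_pvt :]
        return f_pvt + self.back_pvt(m_pvt), f_cnn + self.back_cnn(m_cnn)


@dataclass
class HybridOutputs:
    """The three logit heads plus per-stage maps kept for visualization."""

    logits_pvt: Tensor
    logits_cnn: Tensor
    logits_combine: Tensor
    pvt_maps: list = field(default_factory=list)        # pre-fusion, stages 1-4
    cnn_maps: list = field(default_factory=list)
    fused_pvt_maps: list = field(default_factory=list)  # post-fusion, stages 1-3
    fused_cnn_maps: list = field(default_factory=list)
    concat_map: Tensor | None = None                    # stage-4 channel concat


class PHF3Net(nn.Module):
    """Dual-branch hybrid classifier with stage-wise fusion and an SOP head.

    Parameters
    ----------
    pvt_configs, cnn_config : stage plans for the two branches (defaults:
        the published plans; pass the tiny plans for desk-scale work).
    num_classes : output classes (4 severity grades by default).
    sop_iterations : Newton–Schulz iteration count L (default 8). L=0 keeps
        the un-rooted covariance; ``sop_mode="gap"`` replaces the SOP head
        with global average pooling (the "no second-order pooling" ablation).
    sop_reduce_channels : optional 1×1 convolution shrinking the concatenated
        stage-4 channels before the covariance (0 = off, the literal design;
        recommended on for CPU-scale work since covariance cost grows as C²).
    ffm_enabled : False degrades the model to two independent branches plus
        the concatenation head (fusion ablation).
    """

    def __init__(self, pvt_configs: list[PvTStageConfig] | None = None,
                 cnn_config: CNNStageConfig | None = None, num_classes: int = 4,
                 sop_iterations: int = 8, sop_reduce_channels: int = 0,
                 sop_mode: str = "sop", ffm_enabled: bool = True, *, rng=None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        if pvt_configs is None:
            pvt_configs = default_pvt_configs()
        if cnn_config is None:
            cnn_config = CNNStageConfig.resnet50()
        if sop_mode not in ("sop", "gap"):
            raise ValueError(f"sop_mode must be 'sop' or 'gap', got {sop_mode!r}")
        self.num_classes = num_classes
        self.sop_iterations = sop_iterations
        self.sop_mode = sop_mode
        self.ffm_enabled = ffm_enabled

        self.pvt = PvTBranch(pvt_configs, rng=rng)
        self.cnn = CNNBranch(cnn_config, rng=rng)

        pvt_dims = [c.embed_dim for c in pvt_configs]
        cnn_dims = list(cnn_config.channels)
        self.ffms = nn.ModuleList(
            [FFM(pvt_dims[i], cnn_dims[i], rng=rng) for i in range(3)]
        )

        self.head_pvt = nn.Linear(pvt_dims[3], num_classes, rng=rng, init="kaiming")
        self.head_cnn = nn.Linear(cnn_dims[3], num_classes, rng=rng, init="kaiming")

        concat_ch = pvt_dims[3] + cnn_dims[3]
        if sop_reduce_channels:
            self.sop_reduce = nn.Conv2d(concat_ch, sop_reduce_channels, 1, rng=rng)
            sop_ch = sop_reduce_channels
        else:
            self.sop_reduce = None
            sop_ch = concat_ch
        self.sop_channels = sop_ch
        feat_len = sop_ch if sop_mode == "gap" else sop_ch * (sop_ch + 1) // 2
        self.head_combine = nn.Linear(feat_len, num_classes, rng=rng, init="kaiming")

    @classmethod
    def tiny(cls, num_classes: int = 4, sop_iterations: int = 8,
             sop_reduce_channels: int = 64, ffm_enabled: bool = True,
             sop_mode: str = "sop", *, rng=None) -> "PHF3Net":
        """Desk-scale preset for 64×64 inputs."""
        return cls(tiny_pvt_configs(), CNNStageConfig.tiny(),
                   num_classes=num_classes, sop_iterations=sop_iterations,
                   sop_reduce_channels=sop_reduce_channels, sop_mode=sop_mode,
                   ffm_enabled=ffm_enabled, rng=rng)

    def combine_head(self, concat_map: Tensor) -> Tensor:
        """Second-order pooling of the stage-4 concatenation → logits."""
        x = concat_map
        if self.sop_reduce is not None:
            x = self.sop_reduce(x)
        if self.sop_mode == "gap":
            feats = x.mean(axis=(2, 3))
        else:
            feats = second_order_pool(x, self.sop_iterations)
        return self.head_combine(feats)

    def forward(self, image: Tensor, keep_maps: bool = False) -> HybridOutputs:
        out = HybridOutputs(None, None, None)
        p = image
        c = self.cnn.stem(image)
        for i in range(4):
            p = self.pvt.stage_forward(i, p)
            c = self.cnn.stage_forward(i, c)
            if keep_maps:
                out.pvt_maps.append(p)
                out.cnn_maps.append(c)
            if i < 3 and self.ffm_enabled:
                p, c = self.ffms[i](p, c)
                if keep_maps:
                    out.fused_pvt_maps.append(p)
                    out.fused_cnn_maps.append(c)
            elif i < 3 and keep_maps:
                out.fused_pvt_maps.append(p)
                out.fused_cnn_maps.append(c)

        out.logits_pvt = self.head_pvt(p.mean(axis=(2, 3)))
        out.logits_cnn = self.head_cnn(c.mean(axis=(2, 3)))
        cat = concat([p, c], axis=1)
        if keep_maps:
            out.concat_map = cat
        self._last_stage4 = (p, c, cat)  # retained for Grad-CAM
        out.logits_combine = self.combine_head(cat)
        return out

    def predict_logits(self, image: Tensor) -> Tensor:
        """Inference logits: the main (combine) head only."""
        return self.forward(image).logits_combine
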