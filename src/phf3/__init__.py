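"""PHF3: dual-branch CNN + pyramid-Transformer hybrid with stage-wise feature
fusion and second-order (covariance) pooling, for 4-class severity grading of
endoscopic images (Mayo endoscopic subscore 0–3)."""

from .autograd import Tensor
from .cnn import CNNBranch, CNNStageConfig
from .fusion import FFM, HybridOutputs, PHF3Net
from .losses import label_smoothing_ce, total_loss
from .metrics import MetricsReport, confusion_matrix, per_class_metrics, roc_auc
from .pvt import (
    PvTBranch,
    PvTStageConfig,
    TokenGrid,
    default_pvt_configs,
    tiny_pvt_configs,
)
from .sop import (
    compute_covariance,
    extract_upper_triangular,
    newton_schulz_iterate,
    post_compensate,
    pre_normalize,
    second_order_pool,
)

__version__ = "0.1.0"

__all__ = [
    "Tensor",
    "CNNBranch",
    "CNNStageConfig",
    "FFM",
    "HybridOutputs",
    "PHF3Net",
    "label_smoothing_ce",
    "total_loss",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "roc_auc",
    "PvTBranch",
    "PvTStageConfig",
    "TokenGrid",
    "default_pvt_configs",
    "tiny_pvt_configs",
    "compute_covariance",
    "pre_normalize",
    "newton_schulz_iterate",
    "post_compensate",
    "extract_upper_triangular",
    "second_order_pool",
    "PHF3Classifier",
]


def __getattr__(name):
    # estimator imports engine lazily to keep `import phf3` light
    if name == "PHF3Classifier":
        from .estimator import PHF3Classifier

        return PHF3Classifier
    raise AttributeError(f"module 'phf3' has no attribute {name!r}")
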