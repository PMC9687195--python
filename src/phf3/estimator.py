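"""scikit-learn style estimator wrapping the hybrid network.

``PHF3Classifier`` follows the usual estimator contract — constructor stores
hyperparameters untouched, ``fit(X, y)`` trains and sets trailing-underscore
attributes, ``predict``/``predict_proba`` use the main (second-order-pooling)
head — so it composes with sklearn pipelines and model selection. ``X`` is a
uint8 ``[N, H, W, 3]`` stack of RGB images; the full preprocessing pipeline
(CLAHE, resize, crops, flips, normalization) runs inside.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig

__all__ = ["PHF3Classifier"]


class PHF3Classifier(BaseEstimator, ClassifierMixin):
    """4-class severity classifier with a dual-branch hybrid backbone.

    Parameters mirror :class:`~phf3.config.RunConfig`; ``preset`` selects the
    architecture scale ("tiny" for desk-scale 64-pixel work, "paper" for the
    full-size model). See the methods note for the meaning and defaults of
    the architecture switches.

    Attributes (after fit)
    ----------------------
    classes_ : sorted unique labels seen in ``y``.
    model_ : the trained :class:`~phf3.fusion.PHF3Net`.
    history_ : per-epoch log (loss, learning rate, accuracies).
    config_ : the resolved :class:`RunConfig`.
    """

    def __init__(self, preset: str = "tiny", epochs: int = 30, batch_size: int = 16,
                 lr: float = 0.05, momentum: float = 0.9, weight_decay: float = 1e-5,
                 lr_decay: float = 0.1, lr_step: int = 10,
                 label_smoothing: float = 0.1, loss_weights=(1.0, 1.0, 2.0),
                 sop_iterations: int = 8, sop_reduce_channels: int = 64,
                 sop_mode: str = "sop", ffm_enabled: bool = True,
                 resize: int = 72, crop: int = 64, flip_p: float = 0.3,
                 clahe_enabled: bool = True, random_state: int = 0,
                 verbose: bool = False):
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_decay = lr_decay
        self.lr_step = lr_step
        self.label_smoothing = label_smoothing
        self.loss_weights = loss_weights
        self.sop_iterations = sop_iterations
        self.sop_reduce_channels = sop_reduce_channels
        self.sop_mode = sop_mode
        self.ffm_enabled = ffm_enabled
        self.resize = resize
        self.crop = crop
        self.flip_p = flip_p
        self.clahe_enabled = clahe_enabled
        self.random_state = random_state
        self.verbose = verbose

    def _config(self, num_classes: int) -> RunConfig:
        return RunConfig(
            preset=self.preset, num_classes=num_classes, epochs=self.epochs,
            batch_size=self.batch_size, lr=self.lr, momentum=self.momentum,
            weight_decay=self.weight_decay, lr_decay=self.lr_decay,
            lr_step=self.lr_step, loss_weights=tuple(self.loss_weights),
            label_smoothing=self.label_smoothing,
            sop_iterations=self.sop_iterations,
            sop_reduce_channels=self.sop_reduce_channels, sop_mode=self.sop_mode,
            ffm_enabled=self.ffm_enabled, resize=self.resize, crop=self.crop,
            flip_p=self.flip_p, clahe_enabled=self.clahe_enabled,
            seed=self.random_state,
        )

    @staticmethod
    def _check_images(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(
                f"expected images [N, H, W, 3], got shape {X.shape}"
            )
        if X.dtype != np.uint8:
            raise ValueError(f"expected uint8 images, got dtype {X.dtype}")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        from .engine import train

        X = self._check_images(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        encoded = np.searchsorted(self.classes_, y)
        config = self._config(len(self.classes_))
        result = train(
            config, X, encoded,
            val_images=X_val,
            val_labels=None if y_val is None else np.searchsorted(self.classes_, y_val),
            verbose=self.verbose,
        )
        self.model_ = result.model
        self.history_ = result.history
        self.config_ = config
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        from .data import preprocess_eval_batch
        from .engine import predict_scores

        check_is_fitted(self, "model_")
        X = self._check_images(X)
        batch = preprocess_eval_batch(X, self.config_.augment_spec())
        return predict_scores(self.model_, batch, self.batch_size)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
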