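"""scikit-learn style estimators wrapping the fusion networks.

:class:`FusionImageClassifier` is the main entry point for programmatic
use: a classifier over image arrays ``X`` of shape (n_samples, H, W, 3)
that composes with sklearn model selection and pipelines.  The heavy
lifting lives in :mod:`dermofuse.fusion` and :mod:`dermofuse.training`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .backbones.tiny import tiny_backbone
from .balance import class_weights as _class_weights
from .fusion import FusionConfig, FusionModel
from .training import TrainConfig, two_phase_train

__all__ = ["FusionImageClassifier"]


class FusionImageClassifier(ClassifierMixin, BaseEstimator):
    """Multi-branch CNN fusion classifier with CBAM attention.

    Parameters
    ----------
    strategy : one of conv_reduce, zero_pad, dense_concat, sum, mean, max.
    feature_maps : per-branch (H, W, C) map geometry for the tiny trainable
        backbones, or None to derive three same-geometry branches from the
        input size (spatial dims divided by 8, channel widths 8/6/8).
    use_cbam : bool or per-branch list.
    class_weight : None or "balanced" (inverse-frequency loss weights).
    All remaining parameters mirror the trainer configuration.
    """

    def __init__(self, strategy: str = "dense_concat",
                 feature_maps=None, backbone_width: int = 8,
                 use_cbam=True, branch_dense_units: int = 32,
                 cbam_reduction: int = 2,
                 phase1_epochs: int = 3, phase2_epochs: int = 15,
                 batch_size: int = 16, lr_phase1: float = 1e-3,
                 lr_phase2: float = 1e-3, class_weight=None,
                 random_state: int = 0):
        self.strategy = strategy
        self.feature_maps = feature_maps
        self.backbone_width = backbone_width
        self.use_cbam = use_cbam
        self.branch_dense_units = branch_dense_units
        self.cbam_reduction = cbam_reduction
        self.phase1_epochs = phase1_epochs
        self.phase2_epochs = phase2_epochs
        self.batch_size = batch_size
        self.lr_phase1 = lr_phase1
        self.lr_phase2 = lr_phase2
        self.class_weight = class_weight
        self.random_state = random_state

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(
                f"X must be (n_samples, H, W, 3); got shape {X.shape}")
        return X

    def _branch_specs(self, input_shape):
        h, w, _ = input_shape
        maps = self.feature_maps
        if maps is None:
            mh, mw = max(1, -(-h // 8)), max(1, -(-w // 8))
            maps = [(mh, mw, 8), (mh, mw, 6), (mh, mw, 8)]
        return [tiny_backbone(self.random_state + i, tuple(m),
                              width=self.backbone_width, name=f"branch{i}")
                for i, m in enumerate(maps)]

    def fit(self, X, y, X_valid=None, y_valid=None):
        X = self._validate_images(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        input_shape = X.shape[1:]
        cfg = FusionConfig(
            strategy=self.strategy,
            backbones=self._branch_specs(input_shape),
            n_classes=len(self.classes_),
            use_cbam=self.use_cbam,
            branch_dense_units=self.branch_dense_units,
            cbam_reduction=self.cbam_reduction,
            seed=self.random_state,
        )
        self.model_ = FusionModel(cfg, input_shape)
        weights = None
        if self.class_weight == "balanced":
            counts = {i: int((y_idx == i).sum())
                      for i in range(len(self.classes_))}
            weights = _class_weights(counts)
        elif isinstance(self.class_weight, dict):
            index = {c: i for i, c in enumerate(self.classes_)}
            weights = {index[k]: v for k, v in self.class_weight.items()}
        tcfg = TrainConfig(
            phase1_epochs=self.phase1_epochs, phase2_epochs=self.phase2_epochs,
            batch_size=self.batch_size, lr_phase1=self.lr_phase1,
            lr_phase2=self.lr_phase2, class_weights=weights,
            seed=self.random_state)
        yv = None
        if X_valid is not None and y_valid is not None and len(X_valid):
            index = {c: i for i, c in enumerate(self.classes_)}
            yv = np.array([index[v] for v in np.asarray(y_valid)])
            X_valid = self._validate_images(X_valid)
        self.history_ = two_phase_train(self.model_, X, y_idx,
                                        X_valid, yv, tcfg)
        self.n_features_in_ = int(np.prod(input_shape))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._validate_images(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
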