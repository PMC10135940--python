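"""Scikit-learn-style estimator wrapping the MSA-ResNet regressor.

``MSAResNetRegressor`` follows the sklearn estimator contract (``fit`` /
``predict`` / ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so it composes with pipelines and model selection.
Inputs are ``(n_samples, 3, input_length)`` channel stacks (PPG, VPG,
APG), or the equivalent flattened 2-D array; targets are ``(n_samples,
2)`` mmHg pairs (SBP, DBP).

Two hyperparameter regimes matter in practice:

* the reference protocol — ``epochs=120, batch_size=1024, lr0=0.001`` —
  sized for tens of thousands of segments on accelerator hardware;
* the small-model regime (``small_defaults()``) — quarter width,
  ``batch_size=64, lr0=0.05, epochs=20`` — sized for a few thousand
  synthetic segments on one CPU.  With mmHg labels and Huber delta = 1
  the loss is MAE-like and its gradients are bounded, so small runs need
  the larger step size.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .model import ModelConfig, MSFEConfig, SEConfig, MSAResNet, predict as _predict
from .train import TrainConfig, train as _train

__all__ = ["MSAResNetRegressor"]


class MSAResNetRegressor(RegressorMixin, BaseEstimator):
    """1-D multi-scale SE-ResNet regressor for joint SBP/DBP estimation.

    Parameters
    ----------
    width_multiplier : float
        Scales every channel count; 1.0 is the full ResNet34-width model,
        0.25 the desk-scale variant.
    blocks_per_stage, stage_channels : tuple
        Residual-stage layout (defaults give the 34-layer configuration).
    regular_kernels, large_kernel, branch_channels : MSFE stem geometry.
    se_reduction : int
        Squeeze-and-excitation bottleneck reduction ratio.
    loss : {'huber', 'mse', 'mae'}
    delta : float
        Huber threshold in mmHg.
    validation_fraction : float
        Fraction of the training data held out to select the best
        checkpoint (lowest mean SBP/DBP MAE); 0 keeps the final weights.
    init_head_bias : bool
        Initialise the output head's bias at the training-label means so
        the network starts from the marginal predictor.
    random_state : int or None
        Seeds weight initialisation and batch shuffling; fits are
        bit-reproducible for a fixed seed.

    Attributes
    ----------
    model_ : MSAResNet
        The fitted network.
    history_ : TrainHistory
        Per-epoch loss/MAE/learning-rate trace.
    config_ : ModelConfig
        The architecture actually built.
    """

    def __init__(
        self,
        width_multiplier: float = 1.0,
        blocks_per_stage: tuple = (3, 4, 6, 3),
        stage_channels: tuple = (64, 128, 256, 512),
        regular_kernels: tuple = (3, 5, 7),
        large_kernel: int = 13,
        branch_channels: int = 16,
        se_reduction: int = 16,
        loss: str = "huber",
        delta: float = 1.0,
        epochs: int = 120,
        batch_size: int = 1024,
        lr0: float = 0.001,
        eta_min: float = 0.0,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        validation_fraction: float = 0.1,
        init_head_bias: bool = True,
        random_state: int | None = None,
    ):
        self.width_multiplier = width_multiplier
        self.blocks_per_stage = blocks_per_stage
        self.stage_channels = stage_channels
        self.regular_kernels = regular_kernels
        self.large_kernel = large_kernel
        self.branch_channels = branch_channels
        self.se_reduction = se_reduction
        self.loss = loss
        self.delta = delta
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.eta_min = eta_min
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.validation_fraction = validation_fraction
        self.init_head_bias = init_head_bias
        self.random_state = random_state

    @classmethod
    def small_defaults(cls, **overrides) -> "MSAResNetRegressor":
        """Quarter-width, CPU-scale configuration (see module docstring)."""
        kw = dict(width_multiplier=0.25, epochs=20, batch_size=64, lr0=0.05)
        kw.update(overrides)
        return cls(**kw)

    # -- shaping ------------------------------------------------------------

    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            if X.shape[1] % 3:
                raise ValueError(
                    f"2-D input must have a multiple of 3 columns, got {X.shape[1]}"
                )
            X = X.reshape(len(X), 3, X.shape[1] // 3)
        if X.ndim != 3 or X.shape[1] != 3:
            raise ValueError(
                f"expected (n, 3, length) or (n, 3*length) input, got {X.shape}"
            )
        return X

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, log=None):
        X = self._coerce_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError(f"y must be (n, 2) [SBP, DBP] mmHg, got {y.shape}")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        seed = 0 if self.random_state is None else int(self.random_state)
        cfg = ModelConfig(
            in_channels=3,
            input_length=X.shape[2],
            msfe=MSFEConfig(
                regular_kernels=tuple(self.regular_kernels),
                large_kernel=self.large_kernel,
                branch_channels=self.branch_channels,
                out_channels=self.stage_channels[0],
            ),
            se=SEConfig(reduction=self.se_reduction),
            blocks_per_stage=tuple(self.blocks_per_stage),
            stage_channels=tuple(self.stage_channels),
            width_multiplier=self.width_multiplier,
        )
        model = MSAResNet(cfg, seed=seed)
        if self.init_head_bias:
            model.head.b.data[:] = y.mean(axis=0).astype(model.dtype)
        vf = float(self.validation_fraction)
        tcfg = TrainConfig(
            delta=self.delta,
            batch_size=self.batch_size,
            epochs=self.epochs,
            lr0=self.lr0,
            eta_min=self.eta_min,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            loss=self.loss,
            split=(1.0 - vf, vf, 0.0),
            seed=seed,
        )
        self.model_, self.history_ = _train(model, X, y, tcfg, log=log)
        self.config_ = cfg
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("this MSAResNetRegressor instance is not fitted yet")
        X = self._coerce_X(X)
        return _predict(self.model_, X, batch_size=max(self.batch_size, 64))

    def n_parameters(self) -> int:
        if not hasattr(self, "model_"):
            raise AttributeError("this MSAResNetRegressor instance is not fitted yet")
        return self.model_.n_params()
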