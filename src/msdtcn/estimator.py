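"""Scikit-learn style estimator wrapping the segmentation network.

:class:`SkinLesionSegmenter` follows the fit/predict protocol: ``fit`` runs
Adam on the hybrid BCE+Dice objective with best-validation-Dice weight
selection, ``predict`` returns binary masks at the input resolution, and
``score`` returns the mean Dice coefficient, so the estimator composes with
sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import ModelConfig, PreprocConfig, TrainConfig
from .losses import hybrid_loss
from .metrics import aggregate_reports, confusion, metrics
from .model import MSDTCNNet
from .nn import Adam
from .nn.tensor import Tensor, sigmoid
from .preprocessing import augment as _augment
from .preprocessing import batch_to_model_input, resize_normalize
from .synth import Sample

__all__ = ["SkinLesionSegmenter"]


def _as_samples(X, y=None) -> list[Sample]:
    if len(X) == 0:
        raise ValueError("empty input")
    if isinstance(X[0], Sample):
        return list(X)
    if y is None:
        y = [np.zeros(np.asarray(img).shape[:2], np.uint8) for img in X]
    return [Sample(image=np.asarray(img), mask=np.asarray(m).astype(np.uint8),
                   id=f"sample_{i:04d}")
            for i, (img, m) in enumerate(zip(X, y))]


class SkinLesionSegmenter(BaseEstimator):
    """Dual-encoder lesion segmentation model with sklearn semantics.

    Parameters mirror the architecture/optimization defaults: ConvNeXt
    stage depths (3, 3, 27, 3), a 12-layer deformable encoder, Adam with
    learning rate 1e-3 and betas (0.5, 0.999), batch size 4.  ``epochs``
    counts passes over the training data; ``max_steps`` (if set) caps the
    total number of optimization steps; ``early_stop_dice`` (if set) stops
    as soon as the training-batch Dice exceeds the threshold.

    Attributes (after ``fit``)
    --------------------------
    model_ : the fitted network (best-validation weights restored)
    history_ : list of per-step records (loss, training-batch Dice)
    best_val_dice_ : best validation Dice seen (training Dice when no
        validation set is supplied)
    n_iter_ : optimization steps actually run
    """

    def __init__(self, transformer_depth: int = 12,
                 convnext_depths: tuple = (3, 3, 27, 3),
                 decoder_upsample: str = "deconv", dropout: float = 0.1,
                 learning_rate: float = 1e-3,
                 betas: tuple = (0.5, 0.999), weight_decay: float = 0.0,
                 batch_size: int = 4, epochs: int = 100,
                 max_steps: int | None = None,
                 early_stop_dice: float | None = None,
                 augment: bool = True, seed: int = 42, verbose: bool = False):
        self.transformer_depth = transformer_depth
        self.convnext_depths = convnext_depths
        self.decoder_upsample = decoder_upsample
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.betas = betas
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_steps = max_steps
        self.early_stop_dice = early_stop_dice
        self.augment = augment
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def model_config(self) -> ModelConfig:
        return ModelConfig(transformer_depth=self.transformer_depth,
                           convnext_depths=tuple(self.convnext_depths),
                           decoder_upsample=self.decoder_upsample,
                           dropout=self.dropout, seed=self.seed)

    def train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           betas=tuple(self.betas),
                           weight_decay=self.weight_decay,
                           batch_size=self.batch_size, epochs=self.epochs,
                           seed=self.seed)

    @staticmethod
    def _batch_dice(probs: np.ndarray, targets: np.ndarray) -> float:
        preds = (probs > 0.5).astype(np.uint8)
        reports = [metrics(confusion(p[0], t[0].astype(np.uint8)))
                   for p, t in zip(preds, targets)]
        return aggregate_reports(reports).dice

    def fit(self, X, y=None, validation_data=None):
        """Train on images+masks (arrays or :class:`Sample` lists)."""
        train_cfg = self.train_config().validate()
        samples = _as_samples(X, y)
        val_samples = (_as_samples(*validation_data)
                       if validation_data is not None else None)
        preproc = PreprocConfig()
        model = MSDTCNNet(self.model_config())
        opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
                   betas=train_cfg.betas,
                   weight_decay=train_cfg.weight_decay)
        rng = np.random.default_rng(train_cfg.seed)
        n = len(samples)
        steps_per_epoch = max(1, int(np.ceil(n / train_cfg.batch_size)))
        total_steps = (self.max_steps if self.max_steps is not None
                       else train_cfg.epochs * steps_per_epoch)
        self.history_ = []
        self.best_val_dice_ = -1.0
        best_state = model.state_dict()
        step = 0
        stop = total_steps == 0
        while not stop:
            order = rng.permutation(n)
            for b0 in range(0, n, train_cfg.batch_size):
                batch = [samples[i] for i in order[b0: b0 + train_cfg.batch_size]]
                if self.augment:
                    batch = [_augment(s, preproc, rng) for s in batch]
                xb, yb = batch_to_model_input(batch, preproc)
                model.train()
                probs = sigmoid(model.forward(xb))
                loss = hybrid_loss(probs, Tensor(yb))
                loss_val = float(loss.data)
                if not np.isfinite(loss_val):
                    raise FloatingPointError(
                        f"non-finite training loss at step {step}: {loss_val}")
                train_dice = self._batch_dice(probs.data, yb)
                loss.backward(free_memory=True)
                opt.step()
                opt.zero_grad()
                step += 1
                self.history_.append({"step": step, "loss": loss_val,
                                      "train_dice": train_dice})
                if self.verbose:
                    print(f"step {step}: loss {loss_val:.4f} "
                          f"dice {train_dice:.4f}")
                if (self.early_stop_dice is not None
                        and train_dice > self.early_stop_dice):
                    stop = True
                if step >= total_steps:
                    stop = True
                if stop:
                    break
            # end of epoch: validation Dice drives checkpoint selection
            monitor = val_samples if val_samples else samples
            val_dice = self._dataset_dice(model, monitor)
            self.history_[-1]["val_dice"] = val_dice
            if val_dice > self.best_val_dice_:
                self.best_val_dice_ = val_dice
                best_state = model.state_dict()
        if self.best_val_dice_ < 0:  # zero-step fit: keep the initialization
            self.best_val_dice_ = float("nan")
        model.load_state_dict(best_state)
        model.eval()
        self.model_ = model
        self.n_iter_ = step
        return self

    def _dataset_dice(self, model: MSDTCNNet, samples: list[Sample]) -> float:
        reports = []
        for s in samples:
            x, m = resize_normalize(s)
            prob = model.predict_proba(x[None])[0, 0]
            reports.append(metrics(confusion((prob > 0.5).astype(np.uint8), m)))
        return aggregate_reports(reports).dice

    # ------------------------------------------------------------- predict
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-image foreground probability maps at input resolution."""
        self._check_fitted()
        from skimage.transform import resize as sk_resize
        out = []
        for s in _as_samples(X):
            x, _ = resize_normalize(s)
            prob = self.model_.predict_proba(x[None])[0, 0]
            if prob.shape != s.image.shape[:2]:
                prob = sk_resize(prob, s.image.shape[:2], order=1,
                                 preserve_range=True)
            out.append(prob.astype(np.float32))
        return out

    def predict(self, X) -> list[np.ndarray]:
        """Binary masks (0/1 uint8) at input resolution, threshold 0.5."""
        return [(p > 0.5).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient against reference masks."""
        preds = self.predict(_as_samples(X, y))
        reports = [metrics(confusion(p, np.asarray(t).astype(np.uint8)))
                   for p, t in zip(preds, y)]
        return aggregate_reports(reports).dice
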