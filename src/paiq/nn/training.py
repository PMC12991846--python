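"""Training and evaluation of the quality-regression networks.

Supervision comes from full-reference metric scores ("the network learns to
mimic a metric"): :func:`label_dataset` scores every test image of a ladder
manifest against its reference, and :func:`train` fits a model with MAE loss
and Adam (lr 1e-4, batch 16 by default), early-stopping on validation loss
and restoring the best-validation checkpoint.

Multi-output training normalizes each target metric to [0, 1] over the train
split (lower-is-better metrics are negated first so every head shares the
"higher = better" orientation); the joint loss is the unweighted mean of the
per-metric MAE terms, which the plain MAE over the output vector already is.
Evaluation de-normalizes predictions back to native metric scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..core import LadderManifest, load_image, normalize_minmax, validate_pair
from ..fr_metrics import FRConfigs
from ..fr_metrics import compute_metrics
from .engine import Adam, Module, mae_loss

__all__ = [
    "TrainConfig", "EvalReport", "LabelScaler",
    "label_dataset", "load_labelled_arrays", "train", "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 20
    patience: int = 10  # early-stopping patience on validation loss
    seed: int = 0
    k_folds: int = 5  # hyperparameter cross-validation folds


@dataclass(frozen=True)
class EvalReport:
    dataset: str
    mae: float
    spearman: float
    pearson: float
    n: int


@dataclass(frozen=True)
class LabelScaler:
    """Per-metric affine map used for multi-output label normalization."""

    metrics: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    flip: np.ndarray  # True where lower-is-better (negated before scaling)

    @classmethod
    def identity(cls, metric: str) -> "LabelScaler":
        return cls((metric,), np.zeros(1), np.ones(1), np.zeros(1, dtype=bool))

    @classmethod
    def fit(cls, labels: np.ndarray, metrics: tuple[str, ...]) -> "LabelScaler":
        flip = np.array([m in ("GMSD", "MS-GMSD") for m in metrics])
        signed = np.where(flip, -labels, labels)
        lo = signed.min(axis=0)
        hi = signed.max(axis=0)
        hi = np.where(hi - lo < 1e-12, lo + 1.0, hi)
        return cls(tuple(metrics), lo, hi, flip)

    def transform(self, labels: np.ndarray) -> np.ndarray:
        signed = np.where(self.flip, -labels, labels)
        return ((signed - self.lo) / (self.hi - self.lo)).astype(np.float32)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        signed = scaled * (self.hi - self.lo) + self.lo
        return np.where(self.flip, -signed, signed)


def label_dataset(
    manifest: LadderManifest,
    metrics: list[str],
    configs: FRConfigs | None = None,
) -> pd.DataFrame:
    """Ground-truth labels: FR metric value(s) of each test image vs its reference.

    Returns one row per test image with columns ``path, subset, quality_rank``
    plus one column per metric.  Images on which a metric fails are excluded
    with a warning.
    """
    rows = []
    cache: dict[str, object] = {}
    for subset in manifest.subsets:
        for test_path, ref_path in subset.records:
            ref = cache.get(ref_path)
            if ref is None:
                ref = normalize_minmax(load_image(ref_path))
                cache[ref_path] = ref
            test = normalize_minmax(load_image(test_path))
            try:
                pair = validate_pair(ref, test)
                results = compute_metrics(pair, list(metrics), configs)
            except Exception as exc:
                warnings.warn(f"labelling failed for {test_path}: {exc}; row excluded")
                continue
            row = {"path": test_path, "subset": subset.label,
                   "quality_rank": subset.quality_rank}
            row.update({r.metric: r.value for r in results})
            rows.append(row)
    return pd.DataFrame(rows)


def load_labelled_arrays(labels: pd.DataFrame, metrics: list[str]):
    """Stack the labelled images into (N, H, W, 1) float32 plus (N, M) targets."""
    imgs = []
    for path in labels["path"]:
        img = normalize_minmax(load_image(path))
        imgs.append(img.pixels.astype(np.float32))
    X = np.stack(imgs)[:, :, :, None]
    y = labels[list(metrics)].to_numpy(dtype=np.float64)
    return X, y


def _epoch_pass(model, X, y, opt, batch_size, order):
    total = 0.0
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        model.zero_grad()
        pred = model.forward(X[idx], training=True)
        loss, grad = mae_loss(pred, y[idx])
        model.backward(grad)
        opt.step()
        total += loss * len(idx)
    return total / len(order)


def _val_loss(model, X, y, batch_size=64):
    total = 0.0
    for start in range(0, len(X), batch_size):
        pred = model.forward(X[start : start + batch_size], training=False)
        total += float(np.abs(pred - y[start : start + batch_size]).sum())
    return total / y.size


def train(
    model: Module,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig | None = None,
    scaler: LabelScaler | None = None,
):
    """Fit with MAE loss + Adam; early-stop on validation loss.

    ``y`` arrays are raw metric values (N, M); when a scaler is given the
    targets are normalized with it (fit it on the train split).  Returns
    ``(model, history)`` with the best-validation-loss weights restored.
    """
    cfg = cfg or TrainConfig()
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("empty train or validation split")
    if len(X_train) != len(y_train) or len(X_val) != len(y_val):
        raise ValueError("label/image count mismatch")
    yt = scaler.transform(y_train) if scaler else y_train.astype(np.float32)
    yv = scaler.transform(y_val) if scaler else y_val.astype(np.float32)
    if yt.ndim == 1:
        yt, yv = yt[:, None], yv[:, None]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_train))
        train_loss = _epoch_pass(model, X_train, yt, opt, cfg.batch_size, order)
        val_loss = _val_loss(model, X_val, yv)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, history


def predict(model: Module, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, len(X), batch_size):
        preds.append(model.forward(X[start : start + batch_size], training=False))
    return np.concatenate(preds, axis=0)


def evaluate(
    model: Module,
    X: np.ndarray,
    y: np.ndarray,
    dataset: str = "test",
    scaler: LabelScaler | None = None,
    output_index: int = 0,
) -> EvalReport:
    """Per-dataset MAE / Spearman / Pearson on native metric scale."""
    pred = predict(model, X)
    if scaler is not None:
        pred = scaler.inverse(pred)
    pred1 = np.asarray(pred)[:, output_index].astype(np.float64)
    true1 = (y[:, output_index] if y.ndim > 1 else y).astype(np.float64)
    mae = float(np.abs(pred1 - true1).mean())
    if np.std(pred1) == 0 or np.std(true1) == 0:
        warnings.warn("constant predictions or labels; correlations reported as 0")
        rho = r = 0.0
    else:
        rho = float(stats.spearmanr(pred1, true1).statistic)
        r = float(stats.pearsonr(pred1, true1).statistic)
    return EvalReport(dataset=dataset, mae=mae, spearman=rho, pearson=r, n=len(true1))
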