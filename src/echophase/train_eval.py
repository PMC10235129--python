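"""Training loop, evaluation metrics and the experiment harnesses.

Training follows a fixed recipe: Adam with learning rate 1e-5 and batch
size 10, a stratified validation split (default 10% of the training data),
no early stopping, and a per-epoch history of train/validation loss and
ROC AUC. Evaluation reports AUC, the configured loss on the held-out
batch, and precision/recall (threshold 0.5 for the binary task, argmax and
macro averaging for the 3-class task). Harnesses cover stratified k-fold
cross-validation, the beta sensitivity sweep, and the crop-vs-no-crop
ablation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cropping import CropMidpoints, compute_midpoints, crop_region
from .errors import (ConfigError, DegenerateDataError, DomainError,
                     UndefinedMetricError)
from .network import (Adam, LossConfig, ModelConfig, PhaseNet, build_model,
                      loss_and_grad)
from .preprocess import AugmentConfig, augment, denoise_mean, rescale, resize_to
from .synthetic import FrameRecord, Phase

__all__ = [
    "TrainConfig", "Metrics", "prepare_arrays", "train", "roc_auc",
    "evaluate", "kfold_cv", "beta_sweep", "ablate_cropping",
]

#: canonical phase order used when mapping labels to class indices
PHASE_ORDER = (Phase.ES, Phase.ED, Phase.NONESED)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the training recipe)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 10
    epochs: int = 50
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if not (0 < self.validation_fraction < 1):
            raise ConfigError("validation_fraction must be in (0, 1)")


@dataclass
class Metrics:
    """One evaluation's summary plus the per-epoch training history."""

    auc: float
    loss: float
    precision: float
    recall: float
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "loss": self.loss,
                "precision": self.precision, "recall": self.recall}


# ---------------------------------------------------------------------------
# data preparation


def prepare_arrays(records: list[FrameRecord], *, height: int = 150,
                   width: int = 150, mids: CropMidpoints | None = None,
                   half_width: int | str = "full", denoise_kernel: int = 1,
                   augment_cfg: AugmentConfig | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Turn frame records into a model-ready tensor and integer labels.

    Each frame is (optionally) cropped with the dataset midpoints,
    rescaled to [0, 1], resized to the model input, (optionally) mean
    filtered, and (optionally) augmented. Class indices follow the phase
    order ES=0, ED=1, Non-ESED=2, compacted over the phases present.
    """
    if not records:
        raise DegenerateDataError("no frames provided")
    present = [p for p in PHASE_ORDER if any(r.label is p for r in records)]
    class_index = {p: i for i, p in enumerate(present)}
    xs, ys = [], []
    for rec in records:
        img = rec.image
        if mids is not None:
            img = crop_region(img, mids, half_width)
        if augment_cfg is not None:
            if rng is None:
                rng = np.random.default_rng(augment_cfg.seed)
            arr = augment(img, augment_cfg, rng)
        else:
            arr = rescale(img)
        arr = resize_to(arr, height, width)
        if denoise_kernel > 1:
            arr = denoise_mean(arr, denoise_kernel)
        xs.append(arr.astype(np.float32))
        ys.append(class_index[rec.label])
    x = np.stack(xs)[..., None]
    return x, np.asarray(ys, dtype=np.int64)


def _targets(y: np.ndarray, n_classes: int) -> np.ndarray:
    """0/1 column for binary; one-hot rows for 3-class."""
    if n_classes == 2:
        return y.astype(np.float32)[:, None]
    return np.eye(n_classes, dtype=np.float32)[y]


def _scores(probs: np.ndarray) -> np.ndarray:
    return probs[:, 0] if probs.shape[1] == 1 else probs


# ---------------------------------------------------------------------------
# metrics


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half; computed with midranks, so it
    matches the all-pairs definition exactly and is invariant under any
    strictly monotone transform of the scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise DomainError("labels and scores must be equal-length 1-D vectors")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: need both classes present")
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _macro_ovr_auc(y: np.ndarray, probs: np.ndarray) -> float:
    aucs = [roc_auc((y == c).astype(int), probs[:, c])
            for c in range(probs.shape[1])]
    return float(np.mean(aucs))


def evaluate(model: PhaseNet, data, loss_cfg: LossConfig | None = None,
             threshold: float = 0.5) -> Metrics:
    """Score a model on held-out frames.

    ``data`` is either ``(x, y)`` arrays or a list of records. Binary:
    AUC, configured loss on the batch, precision and recall at the
    threshold. 3-class: macro one-vs-rest AUC and macro precision/recall
    at argmax. With no positive predictions precision is reported as 0
    with a warning.
    """
    loss_cfg = loss_cfg or LossConfig()
    x, y = data if isinstance(data, tuple) else prepare_arrays(data)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("evaluation data must contain >= 2 classes")
    probs = model.predict_proba(x)
    t = _targets(y, model.cfg.n_classes)
    loss_value, _ = loss_and_grad(loss_cfg, t, probs.astype(np.float64))
    if model.cfg.n_classes == 2:
        scores = _scores(probs)
        auc = roc_auc(y, scores)
        pred = (scores >= threshold).astype(int)
        if pred.sum() == 0:
            warnings.warn("no positive predictions; precision reported as 0")
        prec = float(precision_score(y, pred, zero_division=0))
        rec = float(recall_score(y, pred, zero_division=0))
    else:
        auc = _macro_ovr_auc(y, probs)
        pred = probs.argmax(axis=1)
        prec = float(precision_score(y, pred, average="macro", zero_division=0))
        rec = float(recall_score(y, pred, average="macro", zero_division=0))
    return Metrics(auc=auc, loss=float(loss_value), precision=prec, recall=rec)


# ---------------------------------------------------------------------------
# training


def _epoch_metrics(model: PhaseNet, x, y, t, loss_cfg) -> tuple[float, float]:
    probs = model.predict_proba(x)
    value, _ = loss_and_grad(loss_cfg, t, probs.astype(np.float64))
    if model.cfg.n_classes == 2:
        auc = roc_auc(y, _scores(probs))
    else:
        auc = _macro_ovr_auc(y, probs)
    return float(value), auc


def _regularizer(model: PhaseNet, loss_cfg: LossConfig,
                 apply_grads: bool) -> float:
    if loss_cfg.weight_regularizer == "none":
        return 0.0
    lam = loss_cfg.regularizer_strength
    value = 0.0
    layers = [model.conv1, model.conv2, model.conv3, model.dense, model.output]
    for layer in layers:
        w = layer.W
        if loss_cfg.weight_regularizer == "L1":
            value += lam * float(np.abs(w).sum())
            if apply_grads:
                layer.dW += (lam * np.sign(w)).astype(layer.dW.dtype)
        else:
            value += lam * float((w * w).sum())
            if apply_grads:
                layer.dW += (2.0 * lam * w).astype(layer.dW.dtype)
    return value


def train(model: PhaseNet, data, loss_cfg: LossConfig | None = None,
          cfg: TrainConfig | None = None,
          val_data=None) -> pd.DataFrame:
    """Fit the model in place and return the per-epoch history.

    ``data`` is ``(x, y)`` arrays or a list of records. A stratified
    validation split of ``validation_fraction`` is carved out unless
    ``val_data`` is supplied. With ``epochs=0`` the model is returned
    untouched and the history is empty.
    """
    loss_cfg = loss_cfg or LossConfig()
    cfg = cfg or TrainConfig()
    x, y = data if isinstance(data, tuple) else prepare_arrays(data)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training data must contain >= 2 classes")
    if val_data is None:
        idx_tr, idx_val = train_test_split(
            np.arange(len(y)), test_size=cfg.validation_fraction,
            random_state=cfg.seed, stratify=y)
        x_tr, y_tr, x_val, y_val = x[idx_tr], y[idx_tr], x[idx_val], y[idx_val]
    else:
        x_tr, y_tr = x, y
        x_val, y_val = (val_data if isinstance(val_data, tuple)
                        else prepare_arrays(val_data))
    t_tr = _targets(y_tr, model.cfg.n_classes)
    t_val = _targets(y_val, model.cfg.n_classes)

    opt = Adam(model, learning_rate=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    n = len(y_tr)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            probs = model.forward(x_tr[sel], train=True)
            _, dp = loss_and_grad(loss_cfg, t_tr[sel],
                                  probs.astype(np.float64))
            model.backward(dp.astype(np.float32))
            _regularizer(model, loss_cfg, apply_grads=True)
            opt.step(model)
        tr_loss, tr_auc = _epoch_metrics(model, x_tr, y_tr, t_tr, loss_cfg)
        val_loss, val_auc = _epoch_metrics(model, x_val, y_val, t_val, loss_cfg)
        reg = _regularizer(model, loss_cfg, apply_grads=False)
        rows.append({"epoch": epoch + 1, "train_loss": tr_loss + reg,
                     "train_auc": tr_auc, "val_loss": val_loss + reg,
                     "val_auc": val_auc})
    return pd.DataFrame(rows, columns=["epoch", "train_loss", "train_auc",
                                       "val_loss", "val_auc"])


# ---------------------------------------------------------------------------
# harnesses


def kfold_cv(data, k: int = 5, loss_cfg: LossConfig | None = None,
             train_cfg: TrainConfig | None = None,
             model_cfg: ModelConfig | None = None) -> tuple[Metrics, list[Metrics]]:
    """Stratified k-fold cross-validation; returns the fold mean and the
    per-fold metrics."""
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    x, y = data if isinstance(data, tuple) else prepare_arrays(data)
    counts = np.bincount(y)
    if counts.min() < k:
        raise DegenerateDataError(
            f"every class needs >= {k} members for {k}-fold CV")
    model_cfg = model_cfg or ModelConfig(n_classes=len(np.unique(y)))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=train_cfg.seed)
    fold_metrics = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        model = build_model(model_cfg, seed=train_cfg.seed + fold)
        hist = train(model, (x[tr], y[tr]), loss_cfg, train_cfg)
        m = evaluate(model, (x[te], y[te]), loss_cfg)
        m.history = hist
        fold_metrics.append(m)
    mean = Metrics(
        auc=float(np.mean([m.auc for m in fold_metrics])),
        loss=float(np.mean([m.loss for m in fold_metrics])),
        precision=float(np.mean([m.precision for m in fold_metrics])),
        recall=float(np.mean([m.recall for m in fold_metrics])),
    )
    return mean, fold_metrics


def beta_sweep(data, betas: list[float],
               train_cfg: TrainConfig | None = None,
               model_cfg: ModelConfig | None = None,
               test_data=None) -> pd.DataFrame:
    """Train one model per beta value with a common seed and splits and
    tabulate (beta, auc, loss, precision, recall), sorted by beta.

    Per-row failures are recorded in an ``error`` column and the sweep
    continues.
    """
    if not betas:
        raise ConfigError("betas must be nonempty")
    if any(b <= 0 for b in betas):
        raise ConfigError("all beta values must be > 0")
    if len(set(betas)) != len(betas):
        warnings.warn("duplicate beta values in sweep; duplicate rows kept")
    train_cfg = train_cfg or TrainConfig()
    x, y = data if isinstance(data, tuple) else prepare_arrays(data)
    model_cfg = model_cfg or ModelConfig(n_classes=len(np.unique(y)))
    if test_data is None:
        tr, te = train_test_split(np.arange(len(y)), test_size=0.25,
                                  random_state=train_cfg.seed, stratify=y)
        data_tr, data_te = (x[tr], y[tr]), (x[te], y[te])
    else:
        data_tr = (x, y)
        data_te = (test_data if isinstance(test_data, tuple)
                   else prepare_arrays(test_data))
    rows = []
    for beta in sorted(betas):
        row = {"beta": beta}
        try:
            loss_cfg = LossConfig(kind="custom", beta=beta)
            model = build_model(model_cfg, seed=train_cfg.seed)
            train(model, data_tr, loss_cfg, train_cfg)
            m = evaluate(model, data_te, loss_cfg)
            row.update(m.as_dict())
            row["error"] = ""
        except Exception as exc:  # record and continue the sweep
            row.update({"auc": np.nan, "loss": np.nan, "precision": np.nan,
                        "recall": np.nan, "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["beta", "auc", "loss", "precision",
                                       "recall", "error"])


def ablate_cropping(records: list[FrameRecord],
                    loss_cfg: LossConfig | None = None,
                    train_cfg: TrainConfig | None = None,
                    model_cfg: ModelConfig | None = None,
                    half_width: int | str = "full",
                    test_fraction: float = 0.25,
                    mids: CropMidpoints | None = None) -> dict[str, Metrics | dict]:
    """Train and evaluate identical configurations on raw vs cropped frames.

    Midpoints are computed from the training split's tracings only (unless
    supplied explicitly) and applied unchanged to the held-out frames.
    Returns the two metric sets and their differences (cropped minus
    uncropped).
    """
    from .errors import MissingMetadataError
    if any(r.tracing is None for r in records):
        raise MissingMetadataError("every record needs an LV tracing")
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    labels = np.array([PHASE_ORDER.index(r.label) for r in records])
    model_cfg = model_cfg or ModelConfig(n_classes=len(np.unique(labels)))
    idx_tr, idx_te = train_test_split(np.arange(len(records)),
                                      test_size=test_fraction,
                                      random_state=train_cfg.seed,
                                      stratify=labels)
    rec_tr = [records[i] for i in idx_tr]
    rec_te = [records[i] for i in idx_te]
    h = rec_tr[0].image.shape[0]
    if mids is None:
        mids = compute_midpoints([r.tracing for r in rec_tr], image_height=h)
    hw, ww = model_cfg.input_shape[:2]
    out: dict[str, Metrics | dict] = {"midpoints": mids}
    for arm, arm_mids in (("uncropped", None), ("cropped", mids)):
        x_tr, y_tr = prepare_arrays(rec_tr, height=hw, width=ww,
                                    mids=arm_mids, half_width=half_width)
        x_te, y_te = prepare_arrays(rec_te, height=hw, width=ww,
                                    mids=arm_mids, half_width=half_width)
        model = build_model(model_cfg, seed=train_cfg.seed)
        hist = train(model, (x_tr, y_tr), loss_cfg, train_cfg)
        m = evaluate(model, (x_te, y_te), loss_cfg)
        m.history = hist
        out[arm] = m
    out["difference"] = {
        key: out["cropped"].as_dict()[key] - out["uncropped"].as_dict()[key]
        for key in ("auc", "loss", "precision", "recall")}
    return out
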