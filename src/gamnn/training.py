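"""Class-weighted training and 5-fold cross-validated grid search.

In-hospital mortality is rare (<1%), so the cross-entropy loss weights each
positive sample 100x relative to a negative.  Optimization is mini-batch
Adam (default parameters, lr 1e-3) with a reduce-on-plateau schedule: when
the monitored loss has not improved for five consecutive epochs the learning
rate is divided by 10 (down to a small floor).  Training always runs to
``max_epochs`` unless ``early_stop`` is explicitly enabled.

Hyperparameters are selected by exhaustive grid search under stratified
5-fold cross-validation on the training partition, scored by mean held-out
fold AUC; the winning configuration is then retrained on all training rows
(the retrain monitors training loss for the schedule, since no validation
split remains).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import GamnnConfig, GamnnModel, build_model, sigmoid
from .schema import Dataset, FeatureSchema

__all__ = [
    "TrainLog",
    "GridSearchResult",
    "weighted_cross_entropy",
    "train",
    "kfold_indices",
    "grid_search_cv",
    "expand_grid",
    "default_grid",
]

PROB_CLAMP = 1e-7  # probabilities clamped to [eps, 1-eps] inside the loss


def weighted_cross_entropy(y, p, w_pos: float):
    """Per-sample class-weighted cross-entropy on the probability scale.

    y=1 costs ``w_pos * (-ln p)``; y=0 costs ``-ln(1-p)``.  Accepts scalars
    or arrays (elementwise); batch losses are means of these values.
    """
    if w_pos <= 0:
        raise ValueError("positive class weight must be > 0")
    y_arr = np.asarray(y, dtype=float)
    p_arr = np.clip(np.asarray(p, dtype=float), PROB_CLAMP, 1.0 - PROB_CLAMP)
    loss = -(w_pos * y_arr * np.log(p_arr) + (1.0 - y_arr) * np.log1p(-p_arr))
    return float(loss) if loss.ndim == 0 else loss


@dataclass
class TrainLog:
    """Per-epoch record of losses and the learning-rate schedule."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float | None] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_losses)

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,train_loss,val_loss,lr"]
        for i, (tl, vl, lr) in enumerate(
            zip(self.train_losses, self.val_losses, self.learning_rates), start=1
        ):
            vs = "" if vl is None else repr(vl)
            lines.append(f"{i},{tl!r},{vs},{lr!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def _l2_penalty(model: GamnnModel) -> float:
    lam = model.config.l2_lambda
    if lam == 0.0:
        return 0.0
    total = 0.0
    for k, v in model.params.items():
        if k.startswith("hW") or k in ("V", "w"):
            total += float((v * v).sum())
    return lam * total


def _full_loss(model: GamnnModel, ds: Dataset, w_pos: float) -> float:
    """Inference-mode objective (weighted CE mean + L2 penalty)."""
    logits = model.forward_logits(ds.values)
    p = sigmoid(logits)
    return float(np.mean(weighted_cross_entropy(ds.labels, p, w_pos))) + _l2_penalty(model)


class _Adam:
    """Adam with the conventional defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            params[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + eps)


def train(
    model: GamnnModel,
    train_ds: Dataset,
    config: GamnnConfig | None = None,
    val_ds: Dataset | None = None,
) -> tuple[GamnnModel, TrainLog]:
    """Fit the model in place with class-weighted mini-batch Adam.

    The plateau schedule monitors validation loss when ``val_ds`` is given
    and training loss otherwise (the final retrain on all training data has
    no validation split).  Deterministic given ``config.seed``: epoch
    shuffling and dropout masks are drawn from seeded generators.
    """
    cfg = config or model.config
    y = train_ds.labels
    n = train_ds.n_samples
    if n == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if train_ds.has_missing():
        raise ValueError("training data contain missing values; preprocess first")

    w_pos = cfg.positive_class_weight
    lam = cfg.l2_lambda
    X = train_ds.values
    rng_shuffle = np.random.default_rng((cfg.seed, 1))
    rng_dropout = np.random.default_rng((cfg.seed, 2))

    if cfg.intercept_warm_start:
        # start the logistic intercept at the class-weighted base log-odds so
        # the global offset need not travel through the feature channels
        # (which would bias per-feature contributions by shared constants)
        pi = float(y.mean())
        model.params["b0"] = np.asarray(np.log(w_pos * pi / (1.0 - pi)))

    opt = _Adam(model.params)
    log = TrainLog()
    lr = cfg.learning_rate
    best = np.inf
    wait = 0
    weight_keys = [k for k in model.params if k.startswith("hW") or k in ("V", "w")]

    for _epoch in range(cfg.max_epochs):
        order = rng_shuffle.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X[idx], y[idx].astype(float)
            nb = len(idx)
            sample_w = np.where(yb == 1.0, w_pos, 1.0)

            holder = {}

            def dlogit_fn(logit, yb=yb, sample_w=sample_w, nb=nb, holder=holder):
                p = sigmoid(logit)
                holder["loss"] = float(
                    np.mean(weighted_cross_entropy(yb, p, w_pos))
                )
                return sample_w * (p - yb) / nb

            # sum-to-zero identifiability device: per-feature shape offsets
            # are interchangeable with the intercept, so each bottleneck's
            # batch-mean output is penalized toward zero (the GAM-NN
            # analogue of centering every smooth in a classical GAM)
            dG_extra = None
            if cfg.center_penalty > 0.0:
                mu = cfg.center_penalty

                def dG_extra(G, mu=mu):
                    return (2.0 * mu / G.shape[0]) * G.mean(axis=0, keepdims=True)

            _, grads = model.forward_backward(
                Xb, dlogit_fn, training=True, rng=rng_dropout, dG_extra=dG_extra
            )
            if lam > 0.0:
                for k in weight_keys:
                    grads[k] = grads[k] + 2.0 * lam * model.params[k]
            opt.step(model.params, grads, lr)
            batch_losses.append(holder["loss"] + _l2_penalty(model))

        train_loss = float(np.mean(batch_losses))
        val_loss = _full_loss(model, val_ds, w_pos) if val_ds is not None else None
        log.train_losses.append(train_loss)
        log.val_losses.append(val_loss)
        log.learning_rates.append(lr)

        monitored = val_loss if val_loss is not None else train_loss
        if monitored < best - cfg.lr_min_delta:
            best = monitored
            wait = 0
        else:
            wait += 1
            if wait >= cfg.lr_patience_epochs:
                if cfg.early_stop:
                    break
                if lr > cfg.min_learning_rate:
                    lr = max(lr / cfg.lr_reduce_factor, cfg.min_learning_rate)
                wait = 0
    return model, log


def kfold_indices(
    n: int, k: int, labels: np.ndarray, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold validation indices.

    Folds partition 0..n-1; per-fold positive counts differ by at most one.
    Stratification matters at sub-1% prevalence where plain folds can end up
    with zero positives and an undefined fold AUC.
    """
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels length must equal n")
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros((n, 1)), labels)]


def default_grid(**overrides) -> list[GamnnConfig]:
    """The full assessed hyperparameter grid: layers 1-4, sizes
    {10,40,50,90,100}, activations {relu,tanh}, dropout {0.25,0.5,0.9},
    L2 {1e-3,1e-4} — 240 combinations."""
    return expand_grid(
        {
            "n_hidden_layers": [1, 2, 3, 4],
            "layer_size": [10, 40, 50, 90, 100],
            "hidden_activation": ["relu", "tanh"],
            "dropout_p": [0.25, 0.5, 0.9],
            "l2_lambda": [0.001, 0.0001],
        },
        **overrides,
    )


def expand_grid(axes: dict[str, list], **fixed) -> list[GamnnConfig]:
    """Cartesian product of per-hyperparameter value lists -> config list."""
    names = list(axes)
    combos = itertools.product(*(axes[n] for n in names))
    return [GamnnConfig(**dict(zip(names, combo)), **fixed) for combo in combos]


@dataclass
class GridSearchResult:
    """All evaluated combinations plus the selected, fully retrained model."""

    configs: list[GamnnConfig]
    fold_aucs: list[list[float]]
    mean_aucs: list[float]
    selected_index: int
    best_model: GamnnModel
    k: int
    seed: int

    @property
    def best_config(self) -> GamnnConfig:
        return self.configs[self.selected_index]


def grid_search_cv(
    train_ds: Dataset,
    schema: FeatureSchema,
    grid: list[GamnnConfig],
    k: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Select hyperparameters by mean stratified k-fold validation AUC.

    Each combination is trained k times, scored on its held-out fold, and the
    highest mean AUC wins (ties broken by grid order).  The winner is then
    retrained on the full training partition before being returned.
    """
    from .evaluation import roc_auc

    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = kfold_indices(train_ds.n_samples, k, train_ds.labels, seed=seed)
    all_idx = np.arange(train_ds.n_samples)

    fold_aucs: list[list[float]] = []
    for ci, cfg in enumerate(grid):
        aucs = []
        for fi, val_idx in enumerate(folds):
            tr_idx = np.setdiff1d(all_idx, val_idx)
            assert np.intersect1d(tr_idx, val_idx).size == 0
            cfg_fold = GamnnConfig.from_dict({**cfg.to_dict(), "seed": cfg.seed + fi})
            try:
                m = build_model(schema, cfg_fold)
                m, _ = train(m, train_ds.subset(tr_idx), val_ds=train_ds.subset(val_idx))
            except Exception as exc:  # annotate with offending combination
                raise RuntimeError(
                    f"grid combination {ci} ({cfg}) failed on fold {fi}: {exc}"
                ) from exc
            scores = m.forward_logits(train_ds.values[val_idx])
            aucs.append(roc_auc(train_ds.labels[val_idx], scores))
        fold_aucs.append(aucs)

    mean_aucs = [float(np.mean(a)) for a in fold_aucs]
    selected = int(np.argmax(mean_aucs))  # argmax keeps the first on ties

    best_model = build_model(schema, grid[selected])
    best_model, _ = train(best_model, train_ds)
    return GridSearchResult(
        configs=list(grid),
        fold_aucs=fold_aucs,
        mean_aucs=mean_aucs,
        selected_index=selected,
        best_model=best_model,
        k=k,
        seed=seed,
    )
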