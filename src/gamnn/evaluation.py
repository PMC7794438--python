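"""Discrimination metrics with bootstrap intervals, and the LR baseline.

AUC ROC is the Mann–Whitney probability that a random positive outranks a
random negative (ties count one half); average precision is the
non-interpolated step sum over the score-ranked list.  Both are delegated to
scikit-learn, which implements exactly these definitions.  95% confidence
intervals use the percentile bootstrap with paired (label, score) resampling,
1000 resamples by default; resamples that lose one class entirely are
redrawn (metric undefined), with a 10x attempt cap.

The reference model is an (effectively) unpenalized logistic regression on
the identical preprocessed features; a very weak L2 (C=1e6) keeps the fit
defined under perfect separation, and coefficients are reported on the
standardized scale the network itself consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .schema import Dataset, FeatureSchema, SchemaError

__all__ = [
    "EvalReport",
    "LrBaseline",
    "roc_auc",
    "average_precision",
    "bootstrap_ci",
    "fit_lr_baseline",
    "evaluate",
]

LR_BASELINE_C = 1e6  # weak L2: 1/C is the penalty strength


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int)


def roc_auc(labels, scores) -> float:
    """P(score_pos > score_neg) with ties counted one half."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def average_precision(labels, scores) -> float:
    """Non-interpolated AP: sum of (R_k - R_{k-1}) * P_k over the ranking."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ValueError("AP undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def bootstrap_ci(
    metric,
    labels,
    scores,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI from paired resamples with replacement.

    Single-class resamples (for which the metric is undefined) are redrawn,
    capped at ``10 * n_bootstrap`` total draws.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    metric(labels, scores)  # raises if undefined on the full sample
    n = len(labels)
    rng = np.random.default_rng(seed)
    values = np.empty(n_bootstrap)
    got = 0
    attempts = 0
    cap = 10 * n_bootstrap
    while got < n_bootstrap:
        if attempts >= cap:
            raise RuntimeError(
                "bootstrap: too many degenerate single-class resamples"
            )
        idx = rng.integers(0, n, size=n)
        attempts += 1
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        values[got] = metric(yb, scores[idx])
        got += 1
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """AUC and AP point estimates with 95% bootstrap intervals."""

    auc: float
    auc_ci: tuple[float, float]
    ap: float
    ap_ci: tuple[float, float]
    n_bootstrap: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "auc": self.auc,
                "auc_ci": list(self.auc_ci),
                "ap": self.ap,
                "ap_ci": list(self.ap_ci),
                "n_bootstrap": self.n_bootstrap,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            auc=float(d["auc"]),
            auc_ci=(float(d["auc_ci"][0]), float(d["auc_ci"][1])),
            ap=float(d["ap"]),
            ap_ci=(float(d["ap_ci"][0]), float(d["ap_ci"][1])),
            n_bootstrap=int(d["n_bootstrap"]),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def evaluate(
    model_scores, labels, n_bootstrap: int = 1000, seed: int = 0
) -> EvalReport:
    """Assemble both metrics plus bootstrap CIs into one report."""
    scores = np.asarray(model_scores, dtype=float)
    return EvalReport(
        auc=roc_auc(labels, scores),
        auc_ci=bootstrap_ci(roc_auc, labels, scores, n_bootstrap, seed),
        ap=average_precision(labels, scores),
        ap_ci=bootstrap_ci(average_precision, labels, scores, n_bootstrap, seed),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


@dataclass
class LrBaseline:
    """Logistic-regression reference fitted on the same preprocessed features."""

    coefficients: dict[str, float]
    intercept: float
    regularization: str
    degenerate_features: list[str]

    def coef(self, name: str) -> float:
        if name not in self.coefficients:
            raise SchemaError(f"unknown feature {name!r}")
        return self.coefficients[name]

    def decision_logits(self, X: np.ndarray, feature_names: list[str]) -> np.ndarray:
        beta = np.array([self.coefficients[n] for n in feature_names])
        return X @ beta + self.intercept


def fit_lr_baseline(
    train_ds: Dataset, schema: FeatureSchema, class_weight=None
) -> LrBaseline:
    """Maximum-likelihood logistic fit with a very weak L2 for stability.

    Constant (zero-information) columns get a near-zero coefficient under
    the regularizer and are flagged in ``degenerate_features``.
    """
    if train_ds.has_missing():
        raise ValueError("LR baseline requires complete (preprocessed) data")
    y = train_ds.labels
    if len(np.unique(y)) < 2:
        raise ValueError("LR baseline requires both classes present")
    lr = LogisticRegression(
        C=LR_BASELINE_C, solver="lbfgs", max_iter=5000, class_weight=class_weight,
    )
    lr.fit(train_ds.values, y)
    degenerate = [
        n
        for j, n in enumerate(train_ds.feature_names)
        if np.ptp(train_ds.values[:, j]) == 0.0
    ]
    return LrBaseline(
        coefficients={
            n: float(c) for n, c in zip(train_ds.feature_names, lr.coef_[0])
        },
        intercept=float(lr.intercept_[0]),
        regularization=f"L2, C={LR_BASELINE_C:g} (weak; for numerical stability)",
        degenerate_features=degenerate,
    )
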