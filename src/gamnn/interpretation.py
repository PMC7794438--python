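"""Interpretability artifacts: shape curves, rankings, patient reports.

The GAM-NN's additive decomposition makes interpretation direct: plotting a
feature's raw value against its per-sample contribution w_j * g_j(x_j)
traces the learned shape function on the log-odds scale, and the matching
LR contribution (coefficient times standardized value) overlays the linear
reference.  The more negative a contribution, the less that value adds to
the predicted risk.  For a single patient, ranking contributions descending
yields a top-k "why this risk" report in raw clinical units.

Contributions are always reported on the logit scale; the intercept is
global and never allocated to a feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import LrBaseline
from .model import ContributionTable, GamnnModel, contributions_table
from .schema import Dataset, SchemaError

__all__ = [
    "ShapeCurve",
    "PatientReport",
    "lr_contribution",
    "shape_curves",
    "rank_features_by_mean_contribution",
    "patient_report",
    "binned_curve",
    "export_shape_curves_tsv",
    "plot_shape_curves",
]


@dataclass
class ShapeCurve:
    """Per-sample (raw value, contribution) pairs for one continuous feature.

    ``raw_values`` are pre-standardization (clinical-units) values for
    readable axes; both models' contributions are on the logit scale.
    """

    feature: str
    raw_values: np.ndarray
    gamnn_contributions: np.ndarray
    lr_contributions: np.ndarray


@dataclass
class PatientReport:
    """Top-k features by contribution for a single sample, raw units."""

    sample_id: int | str
    rows: list[tuple[str, float, float]]  # (feature, raw value, contribution)
    intercept: float
    logit: float

    def to_tsv(self) -> str:
        lines = ["feature\tvalue\tcontribution"]
        for name, value, contrib in self.rows:
            lines.append(f"{name}\t{value:g}\t{contrib:.6g}")
        return "\n".join(lines) + "\n"


def lr_contribution(lr: LrBaseline, x: np.ndarray, feature_names: list[str], name: str) -> float:
    """Coefficient times the (standardized) input value for one feature."""
    if name not in feature_names:
        raise SchemaError(f"unknown feature {name!r}")
    j = feature_names.index(name)
    return lr.coef(name) * float(np.asarray(x, dtype=float)[j])


def shape_curves(
    model: GamnnModel,
    lr: LrBaseline,
    ds: Dataset,
    raw_ds: Dataset,
    features: list[str] | None = None,
) -> list[ShapeCurve]:
    """Learned shape functions for continuous features, GAM-NN vs LR.

    ``ds`` is the preprocessed twin of ``raw_ds`` (same rows, same order);
    the x-axis comes from ``raw_ds``, contributions from each model applied
    to ``ds``.
    """
    if ds.n_samples != raw_ds.n_samples or ds.feature_names != raw_ds.feature_names:
        raise ValueError("ds and raw_ds must be row-aligned with identical columns")
    table = contributions_table(model, ds)
    cont = [
        n for n, k in zip(model.feature_names, model.feature_kinds) if k == "continuous"
    ]
    wanted = cont if features is None else features
    curves = []
    for name in wanted:
        if name not in cont:
            raise SchemaError(f"{name!r} is not a continuous feature")
        j = ds.feature_names.index(name)
        curves.append(
            ShapeCurve(
                feature=name,
                raw_values=raw_ds.values[:, j].copy(),
                gamnn_contributions=table.column(name).copy(),
                lr_contributions=lr.coef(name) * ds.values[:, j],
            )
        )
    return curves


def rank_features_by_mean_contribution(
    table: ContributionTable, continuous_only: bool = False
) -> list[str]:
    """Features sorted by mean contribution across samples, descending.

    ``continuous_only`` drops binary features first — binary shape plots
    show only two x values and are usually uninteresting.
    """
    if table.n_samples == 0:
        raise ValueError("empty contribution table")
    names = table.feature_names
    kinds = table.feature_kinds
    means = table.contributions.mean(axis=0)
    items = [
        (n, m)
        for n, k, m in zip(names, kinds, means)
        if not (continuous_only and k == "binary")
    ]
    items.sort(key=lambda t: -t[1])
    return [n for n, _ in items]


def patient_report(
    model: GamnnModel,
    x_raw: np.ndarray,
    x_prep: np.ndarray,
    k: int = 10,
    sample_id: int | str = 0,
) -> PatientReport:
    """Top-k contributions for one patient, with raw clinical values.

    ``x_prep`` is the preprocessed twin of ``x_raw``.  With k equal to the
    feature count the listed contributions plus the intercept reconstruct
    the patient's full logit.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x_raw = np.asarray(x_raw, dtype=float)
    x_prep = np.asarray(x_prep, dtype=float)
    if x_raw.shape != x_prep.shape or x_raw.shape != (model.n_features,):
        raise ValueError("x_raw and x_prep must both match the model's feature count")
    C, logits = model.contributions(x_prep[None, :])
    contribs = C[0]
    order = np.argsort(-contribs, kind="stable")[: min(k, model.n_features)]
    rows = [
        (model.feature_names[j], float(x_raw[j]), float(contribs[j])) for j in order
    ]
    return PatientReport(
        sample_id=sample_id,
        rows=rows,
        intercept=float(model.params["b0"]),
        logit=float(logits[0]),
    )


def binned_curve(
    raw_values: np.ndarray, contributions: np.ndarray, n_bins: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count binned smoother over a shape-curve scatter.

    Test/diagnostic infrastructure (e.g. locating the argmin of a learned
    U-shape); the primary artifact remains the raw per-sample scatter.
    """
    order = np.argsort(raw_values, kind="stable")
    xs = raw_values[order]
    cs = contributions[order]
    edges = np.linspace(0, len(xs), n_bins + 1).astype(int)
    bx, bc = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            bx.append(xs[a:b].mean())
            bc.append(cs[a:b].mean())
    return np.asarray(bx), np.asarray(bc)


def export_shape_curves_tsv(curves: list[ShapeCurve], path: str | Path) -> None:
    """Tidy TSV: feature, raw_value, gamnn_contribution, lr_contribution."""
    lines = ["feature\traw_value\tgamnn_contribution\tlr_contribution"]
    for c in curves:
        for x, g, l in zip(c.raw_values, c.gamnn_contributions, c.lr_contributions):
            lines.append(f"{c.feature}\t{x!r}\t{g!r}\t{l!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_shape_curves(curves: list[ShapeCurve], path: str | Path, ncols: int = 3) -> None:
    """Dual-axis scatter per feature: GAM-NN contribution on the primary
    y-axis, LR contribution on the secondary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(curves)
    ncols = min(ncols, max(n, 1))
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for i, c in enumerate(curves):
        ax = axes[i // ncols][i % ncols]
        ax.scatter(c.raw_values, c.gamnn_contributions, s=4, color="tab:blue", label="GAM-NN")
        ax2 = ax.twinx()
        ax2.scatter(c.raw_values, c.lr_contributions, s=4, color="tab:green", label="LR")
        ax.set_title(c.feature)
        ax.set_xlabel("feature value")
        ax.set_ylabel("GAM-NN risk contribution", color="tab:blue")
        ax2.set_ylabel("LR risk contribution", color="tab:green")
    for i in range(n, nrows * ncols):
        axes[i // ncols][i % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
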