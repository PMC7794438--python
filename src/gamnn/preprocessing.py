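"""Imputation, clinical clipping, standardization, and the train/test split.

The pipeline order is fixed: impute -> clip -> standardize.  All data-driven
parameters (train-mean imputation values, standardization statistics) are
fitted on training rows only and then applied unchanged to any partition, so
no test-set statistic can leak into preprocessing.

Standardization uses the population (divide-by-n) standard deviation; either
convention is defensible, this one is fixed and documented for
reproducibility.  By default binary 0/1 columns are left on their raw scale —
the additive-contribution formula for binary features (input value times
logistic weight) presupposes 0/1 inputs — but ``standardize_binary=True``
rescales them too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import Dataset, FeatureSchema, SchemaError

__all__ = [
    "SplitIndices",
    "StandardizationStats",
    "train_test_split",
    "train_feature_means",
    "impute",
    "clip_values",
    "standardize_fit",
    "standardize_apply",
    "PreprocessingPipeline",
]


@dataclass(frozen=True)
class SplitIndices:
    """Row indices of a random train/test partition."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_idx": self.train_idx.tolist(),
                "test_idx": self.test_idx.tolist(),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitIndices":
        d = json.loads(text)
        return cls(
            np.asarray(d["train_idx"], dtype=int),
            np.asarray(d["test_idx"], dtype=int),
            int(d["seed"]),
        )


def train_test_split(n: int, train_fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Random split of ``n`` rows with |train| = round(train_fraction * n).

    Deterministic in ``seed``; an 80/20 split of 59,985 rows yields
    47,988 / 11,997.
    """
    if n < 2:
        raise ValueError("need at least 2 rows to form both partitions")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)


def train_feature_means(train_ds: Dataset, schema: FeatureSchema) -> dict[str, float]:
    """Mean of the observed (non-missing) training values for every
    train_mean-policy feature."""
    means: dict[str, float] = {}
    for s in schema.specs:
        if s.impute_policy != "train_mean":
            continue
        col = train_ds.column(s.name)
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise ValueError(
                f"feature {s.name!r} has no observed training values; "
                "train-mean imputation is undefined"
            )
        means[s.name] = float(observed.mean())
    return means


def impute(ds: Dataset, schema: FeatureSchema, train_stats: dict[str, float]) -> Dataset:
    """Fill missing cells per the schema's per-feature policy.

    constant -> the declared constant; zero -> 0 (medication features where
    absence means "not administered"); train_mean -> the training-set mean
    passed in ``train_stats`` (never this dataset's own mean).  Observed
    values are untouched.
    """
    out = ds.copy()
    for j, s in enumerate(schema.specs):
        col = out.values[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if s.impute_policy == "constant":
            fill = float(s.constant_value)  # type: ignore[arg-type]
        elif s.impute_policy == "zero":
            fill = 0.0
        else:
            if s.name not in train_stats:
                raise ValueError(f"train_stats missing mean for feature {s.name!r}")
            fill = train_stats[s.name]
        col[miss] = fill
    return out


def clip_values(ds: Dataset, schema: FeatureSchema) -> Dataset:
    """Clamp each feature into its declared clinically plausible bounds.

    Bounds are domain constants from the schema, never data-derived, and are
    applied identically to every partition.  Features without bounds pass
    through untouched.
    """
    out = ds.copy()
    for j, s in enumerate(schema.specs):
        if s.clip_min is not None or s.clip_max is not None:
            out.values[:, j] = np.clip(
                out.values[:, j],
                -np.inf if s.clip_min is None else s.clip_min,
                np.inf if s.clip_max is None else s.clip_max,
            )
    return out


@dataclass
class StandardizationStats:
    """Per-feature training mean and (population) standard deviation."""

    means: dict[str, float]
    sds: dict[str, float]
    fitted_on: str = "train"

    def to_json(self) -> str:
        return json.dumps(
            {
                "fitted_on": self.fitted_on,
                "features": {
                    n: {"mean": self.means[n], "sd": self.sds[n]} for n in self.means
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardizationStats":
        d = json.loads(text)
        feats = d["features"]
        return cls(
            means={n: float(v["mean"]) for n, v in feats.items()},
            sds={n: float(v["sd"]) for n, v in feats.items()},
            fitted_on=d.get("fitted_on", "train"),
        )


def standardize_fit(
    train_ds: Dataset, schema: FeatureSchema, standardize_binary: bool = False
) -> StandardizationStats:
    """Fit per-feature mean/sd on (complete) training rows.

    Only continuous features are standardized unless ``standardize_binary``.
    A zero-variance feature is an error: it carries no information and would
    divide by zero.
    """
    if train_ds.has_missing():
        raise ValueError("standardize_fit requires complete (imputed) data")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for s in schema.specs:
        if s.kind == "binary" and not standardize_binary:
            continue
        col = train_ds.column(s.name)
        m = float(col.mean())
        sd = float(col.std())  # population sd (ddof=0)
        if sd == 0.0:
            raise ValueError(f"feature {s.name!r} is constant in training data")
        means[s.name] = m
        sds[s.name] = sd
    return StandardizationStats(means=means, sds=sds)


def standardize_apply(ds: Dataset, stats: StandardizationStats) -> Dataset:
    """Rescale with *training* statistics: z = (x - mean_train) / sd_train.

    Applies to any partition; no clipping happens at this stage, so test
    values far outside the training range simply get large |z|.
    """
    out = ds.copy()
    for name in stats.means:
        if name not in out.feature_names:
            continue
        j = out.feature_names.index(name)
        out.values[:, j] = (out.values[:, j] - stats.means[name]) / stats.sds[name]
    missing = [n for n in out.feature_names if n not in stats.means]
    # binary features legitimately absent from stats; a continuous feature
    # absent would silently pass through unscaled, so this is left to the
    # pipeline wrapper which knows the schema
    del missing
    return out


@dataclass
class PreprocessingPipeline:
    """impute -> clip -> standardize, fitted on training rows only."""

    schema: FeatureSchema
    standardize_binary: bool = False
    train_means: dict[str, float] = field(default_factory=dict)
    stats: StandardizationStats | None = None

    def fit(self, train_ds: Dataset) -> "PreprocessingPipeline":
        self.train_means = train_feature_means(train_ds, self.schema)
        complete = clip_values(impute(train_ds, self.schema, self.train_means), self.schema)
        self.stats = standardize_fit(complete, self.schema, self.standardize_binary)
        return self

    def transform(self, ds: Dataset) -> Dataset:
        if self.stats is None:
            raise RuntimeError("pipeline not fitted")
        for name in self.schema.continuous_names:
            if name not in self.stats.means:
                raise SchemaError(f"standardization stats missing feature {name!r}")
        complete = clip_values(impute(ds, self.schema, self.train_means), self.schema)
        return standardize_apply(complete, self.stats)

    def transform_raw(self, ds: Dataset) -> Dataset:
        """Imputed and clipped but *not* standardized — the clinical-units
        twin used for raw-value axes in interpretability outputs."""
        return clip_values(impute(ds, self.schema, self.train_means), self.schema)

    def fit_transform(self, train_ds: Dataset) -> Dataset:
        return self.fit(train_ds).transform(train_ds)

    def to_json(self) -> str:
        if self.stats is None:
            raise RuntimeError("pipeline not fitted")
        return json.dumps(
            {
                "standardize_binary": self.standardize_binary,
                "train_means": self.train_means,
                "stats": json.loads(self.stats.to_json()),
            }
        )

    @classmethod
    def from_json(cls, text: str, schema: FeatureSchema) -> "PreprocessingPipeline":
        d = json.loads(text)
        pipe = cls(schema=schema, standardize_binary=bool(d["standardize_binary"]))
        pipe.train_means = {k: float(v) for k, v in d["train_means"].items()}
        pipe.stats = StandardizationStats.from_json(json.dumps(d["stats"]))
        return pipe


def save_pipeline(pipe: PreprocessingPipeline, path: str | Path) -> None:
    Path(path).write_text(pipe.to_json())


def load_pipeline(path: str | Path, schema: FeatureSchema) -> PreprocessingPipeline:
    return PreprocessingPipeline.from_json(Path(path).read_text(), schema)
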