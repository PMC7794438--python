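"""Feature schemas and dataset containers.

A :class:`FeatureSchema` declares every model input column — whether it is
continuous (gets its own subnetwork) or binary (wired straight into the
logistic layer), how missing values are imputed, and optional clinical
clipping bounds.  A :class:`Dataset` is the single currency passed between
pipeline stages: a float matrix (NaN marks missing values before
imputation), a 0/1 label vector, and the schema-ordered column names.

Data files are plain CSV with a header row; schemas are YAML (or JSON)
documents of the form::

    features:
      - {name: AGE, kind: continuous, impute_policy: train_mean}
      - {name: ASA_SCORE, kind: continuous, impute_policy: constant,
         constant_value: 3}
      - {name: ART_LINE_YN, kind: binary}
    outcome: IN_HOSPITAL_MORTALITY
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "DataValidationError",
    "FeatureSpec",
    "FeatureSchema",
    "Dataset",
    "read_schema",
    "read_dataset",
    "write_dataset",
]

KINDS = ("continuous", "binary")
IMPUTE_POLICIES = ("constant", "zero", "train_mean")


class SchemaError(ValueError):
    """A schema document or schema/data mismatch is invalid."""


class DataValidationError(ValueError):
    """A data file violates the declared schema contract."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single input column."""

    name: str
    kind: str
    impute_policy: str = ""
    constant_value: float | None = None
    clip_min: float | None = None
    clip_max: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if not self.impute_policy:
            # defaults: continuous -> train mean, binary -> absent means zero
            object.__setattr__(
                self,
                "impute_policy",
                "train_mean" if self.kind == "continuous" else "zero",
            )
        if self.impute_policy not in IMPUTE_POLICIES:
            raise SchemaError(
                f"unknown impute_policy {self.impute_policy!r} for {self.name!r}"
            )
        if self.impute_policy == "constant" and self.constant_value is None:
            raise SchemaError(
                f"impute_policy=constant requires constant_value ({self.name!r})"
            )
        if self.clip_min is not None and self.clip_max is not None:
            if not self.clip_min < self.clip_max:
                raise SchemaError(
                    f"clip_min must be < clip_max for {self.name!r} "
                    f"({self.clip_min} >= {self.clip_max})"
                )


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of feature specs plus the outcome column name.

    The declaration order is the column order everywhere downstream.
    """

    specs: tuple[FeatureSpec, ...]
    outcome_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        names = [s.name for s in self.specs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate feature names: {sorted(dupes)}")
        if self.outcome_name in names:
            raise SchemaError(
                f"outcome {self.outcome_name!r} also declared as a feature"
            )
        if not self.specs:
            raise SchemaError("schema declares no features")

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def continuous_names(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "continuous"]

    @property
    def binary_names(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "binary"]

    def spec(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise SchemaError(f"unknown feature {name!r}")

    def to_dict(self) -> dict:
        feats = []
        for s in self.specs:
            d: dict = {"name": s.name, "kind": s.kind, "impute_policy": s.impute_policy}
            if s.constant_value is not None:
                d["constant_value"] = s.constant_value
            if s.clip_min is not None:
                d["clip_min"] = s.clip_min
            if s.clip_max is not None:
                d["clip_max"] = s.clip_max
            feats.append(d)
        return {"features": feats, "outcome": self.outcome_name}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class Dataset:
    """Feature matrix + binary labels + schema-ordered column names.

    ``values`` is float64; NaN encodes a missing cell (allowed only before
    imputation).  ``labels`` is an int array of 0/1.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.values.shape[0],):
            raise DataValidationError("labels length must match number of rows")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            raise DataValidationError(
                f"labels must be 0/1; offending rows {np.where(bad)[0][:5].tolist()}"
            )
        self.labels = self.labels.astype(int)
        if len(self.feature_names) != self.values.shape[1]:
            raise DataValidationError("feature_names length must match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset(self, idx: Sequence[int]) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset(self.values[idx], self.labels[idx], list(self.feature_names))

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), self.labels.copy(), list(self.feature_names))


def read_schema(path: str | Path) -> FeatureSchema:
    """Load a feature schema from a YAML (or JSON) document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "features" not in doc or "outcome" not in doc:
        raise SchemaError(f"{path}: expected keys 'features' and 'outcome'")
    specs = []
    for entry in doc["features"]:
        known = {"name", "kind", "impute_policy", "constant_value", "clip_min", "clip_max"}
        extra = set(entry) - known
        if extra:
            raise SchemaError(f"unknown schema fields {sorted(extra)} in {entry.get('name')!r}")
        specs.append(
            FeatureSpec(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                impute_policy=str(entry.get("impute_policy", "")),
                constant_value=entry.get("constant_value"),
                clip_min=entry.get("clip_min"),
                clip_max=entry.get("clip_max"),
            )
        )
    return FeatureSchema(specs=tuple(specs), outcome_name=str(doc["outcome"]))


def read_dataset(path: str | Path, schema: FeatureSchema) -> Dataset:
    """Read a CSV file against a schema.

    Columns are reordered to schema order; the outcome column may sit
    anywhere in the file.  Empty cells parse as missing.  Binary columns
    accept only 0/1 (or empty); labels must be 0/1.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [n for n in schema.feature_names + [schema.outcome_name] if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {missing_cols}")

    cols = []
    for s in schema.specs:
        raw = df[s.name]
        col = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.isnan(col) & raw.notna().to_numpy() & (raw.astype(str).str.strip() != "").to_numpy()
        if bad.any():
            r = int(np.where(bad)[0][0])
            raise DataValidationError(
                f"{path}: non-numeric value {raw.iloc[r]!r} in column {s.name!r}, row {r}"
            )
        if s.kind == "binary":
            observed = col[~np.isnan(col)]
            if observed.size and not np.isin(observed, (0.0, 1.0)).all():
                off = observed[~np.isin(observed, (0.0, 1.0))][0]
                raise DataValidationError(
                    f"{path}: binary column {s.name!r} contains {off!r}; only 0/1 allowed"
                )
        cols.append(col)
    values = np.column_stack(cols) if cols else np.empty((len(df), 0))

    lab_raw = pd.to_numeric(df[schema.outcome_name], errors="coerce").to_numpy(dtype=float)
    if np.isnan(lab_raw).any():
        r = int(np.where(np.isnan(lab_raw))[0][0])
        raise DataValidationError(f"{path}: missing/non-numeric label at row {r}")
    if not np.isin(lab_raw, (0.0, 1.0)).all():
        off = lab_raw[~np.isin(lab_raw, (0.0, 1.0))][0]
        raise DataValidationError(f"{path}: label value {off!r} outside {{0,1}}")

    return Dataset(values, lab_raw.astype(int), schema.feature_names)


def write_dataset(ds: Dataset, path: str | Path, outcome_name: str = "outcome") -> None:
    """Write a dataset as CSV; missing values become empty cells.

    Serializes floats at full (round-trip) precision so read∘write is the
    identity on valid datasets.
    """
    df = pd.DataFrame(ds.values, columns=ds.feature_names)
    df[outcome_name] = ds.labels
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
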