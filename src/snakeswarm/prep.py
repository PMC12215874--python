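"""Tabular preprocessing: imputation, train/test splitting, and column
transforms (standardization + one-hot encoding) fitted on training data only.

The unit flowing through the pipeline is :class:`TabularDataset` — a feature
frame, a label vector, and a column schema tagging each column as numeric,
binary, categorical, or label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import OneHotEncoder, StandardScaler

__all__ = [
    "ColumnSchema",
    "TabularDataset",
    "SplitPair",
    "ColumnPrep",
    "clean_impute",
    "transform_columns",
    "split_train_test",
    "load_csv",
    "save_csv",
]

KINDS = ("numeric", "binary", "categorical", "label")


@dataclass(frozen=True)
class ColumnSchema:
    name: str
    kind: str
    categories: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")


@dataclass
class TabularDataset:
    """Feature frame + labels + schema; the pipeline's unit of data."""

    X: pd.DataFrame
    y: pd.Series
    schema: list[ColumnSchema]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y row counts differ")
        labels = [s for s in self.schema if s.kind == "label"]
        if len(labels) != 1:
            raise ValueError("schema must contain exactly one label column")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def feature_schema(self) -> list[ColumnSchema]:
        return [s for s in self.schema if s.kind != "label"]

    def class_counts(self) -> dict:
        return self.y.value_counts().to_dict()

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            self.X.copy(), self.y.copy(), list(self.schema), dict(self.provenance)
        )


@dataclass
class SplitPair:
    train: TabularDataset
    test: TabularDataset
    fraction: float


def clean_impute(dataset: TabularDataset) -> TabularDataset:
    """Drop rows with a majority of fields missing, impute the rest.

    Rows missing more than half of their feature cells are removed; remaining
    numeric gaps are filled with the column mean and binary/categorical gaps
    with the column mode.  Duplicate rows are dropped.  Idempotent; counts of
    dropped rows and imputed cells land in ``provenance``.
    """
    X, y = dataset.X.copy(), dataset.y.copy()
    for s in dataset.feature_schema():
        if s.name in X.columns and X[s.name].isna().all():
            raise ValueError(f"unimputable-column: {s.name!r} is entirely missing")

    frac_missing = X.isna().mean(axis=1)
    keep = frac_missing <= 0.5
    n_dropped_missing = int((~keep).sum())
    X, y = X.loc[keep], y.loc[keep]

    dup = pd.concat([X, y.rename("__label__")], axis=1).duplicated()
    n_dropped_dup = int(dup.sum())
    X, y = X.loc[~dup], y.loc[~dup]

    n_imputed = int(X.isna().sum().sum())
    for s in dataset.feature_schema():
        col = X[s.name]
        if not col.isna().any():
            continue
        if s.kind == "numeric":
            X[s.name] = col.fillna(col.mean())
        else:
            X[s.name] = col.fillna(col.mode(dropna=True).iloc[0])

    prov = dict(dataset.provenance)
    prov["clean_impute"] = {
        "rows_dropped_missing": n_dropped_missing,
        "rows_dropped_duplicate": n_dropped_dup,
        "cells_imputed": n_imputed,
    }
    return TabularDataset(
        X.reset_index(drop=True), y.reset_index(drop=True), list(dataset.schema), prov
    )


class ColumnPrep:
    """Standardize numeric columns and one-hot encode categoricals, with all
    statistics fitted on the training partition only.

    Zero-variance numeric columns are scaled by 1 and flagged; categories
    unseen at fit time map to an all-zero one-hot block.
    """

    def __init__(self) -> None:
        self.scaler_: StandardScaler | None = None
        self.encoder_: OneHotEncoder | None = None
        self.numeric_cols_: list[str] = []
        self.binary_cols_: list[str] = []
        self.categorical_cols_: list[str] = []
        self.zero_variance_flags_: list[str] = []

    def fit(self, train: TabularDataset) -> "ColumnPrep":
        self.numeric_cols_ = [s.name for s in train.feature_schema() if s.kind == "numeric"]
        self.binary_cols_ = [s.name for s in train.feature_schema() if s.kind == "binary"]
        self.categorical_cols_ = [
            s.name for s in train.feature_schema() if s.kind == "categorical"
        ]
        if self.numeric_cols_:
            self.scaler_ = StandardScaler().fit(train.X[self.numeric_cols_])
            variances = np.asarray(self.scaler_.var_)
            self.zero_variance_flags_ = [
                c for c, v in zip(self.numeric_cols_, variances) if v == 0.0
            ]
        if self.categorical_cols_:
            self.encoder_ = OneHotEncoder(
                handle_unknown="ignore", sparse_output=False, dtype=float
            ).fit(train.X[self.categorical_cols_].astype(str))
        return self

    @property
    def fitted_means(self) -> dict:
        if self.scaler_ is None:
            return {}
        return dict(zip(self.numeric_cols_, self.scaler_.mean_))

    @property
    def fitted_scales(self) -> dict:
        if self.scaler_ is None:
            return {}
        return dict(zip(self.numeric_cols_, self.scaler_.scale_))

    def transform(self, dataset: TabularDataset) -> TabularDataset:
        blocks: list[pd.DataFrame] = []
        schema: list[ColumnSchema] = []
        if self.numeric_cols_:
            arr = self.scaler_.transform(dataset.X[self.numeric_cols_])
            blocks.append(pd.DataFrame(arr, columns=self.numeric_cols_))
            schema += [ColumnSchema(c, "numeric") for c in self.numeric_cols_]
        if self.binary_cols_:
            arr = dataset.X[self.binary_cols_].astype(float).to_numpy()
            blocks.append(pd.DataFrame(arr, columns=self.binary_cols_))
            schema += [ColumnSchema(c, "binary") for c in self.binary_cols_]
        if self.categorical_cols_:
            arr = self.encoder_.transform(dataset.X[self.categorical_cols_].astype(str))
            names = list(self.encoder_.get_feature_names_out(self.categorical_cols_))
            blocks.append(pd.DataFrame(arr, columns=names))
            schema += [ColumnSchema(c, "binary") for c in names]
        X = pd.concat(blocks, axis=1)
        label = [s for s in dataset.schema if s.kind == "label"][0]
        prov = dict(dataset.provenance)
        if self.zero_variance_flags_:
            prov["zero_variance_columns"] = list(self.zero_variance_flags_)
        return TabularDataset(
            X, dataset.y.reset_index(drop=True), schema + [label], prov
        )


def transform_columns(train: TabularDataset, apply_to: TabularDataset) -> TabularDataset:
    """Transform ``apply_to`` using statistics fitted on ``train`` only."""
    return ColumnPrep().fit(train).transform(apply_to)


def split_train_test(
    dataset: TabularDataset, fraction: float = 0.8, seed: int = 0
) -> SplitPair:
    """Stratified train/test split preserving per-class proportions."""
    counts = dataset.y.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"unsplittable-class: classes with one member: {bad}")
    idx_train, idx_test = train_test_split(
        np.arange(dataset.n_samples),
        train_size=fraction,
        stratify=dataset.y,
        random_state=int(seed) % (2**32),
    )
    def _take(idx: np.ndarray) -> TabularDataset:
        return TabularDataset(
            dataset.X.iloc[idx].reset_index(drop=True),
            dataset.y.iloc[idx].reset_index(drop=True),
            list(dataset.schema),
            dict(dataset.provenance),
        )
    return SplitPair(train=_take(idx_train), test=_take(idx_test), fraction=fraction)


def load_csv(csv_path: str | Path, schema_path: str | Path | None = None) -> TabularDataset:
    """Read a header CSV plus optional YAML schema sidecar (name -> kind).

    Without a sidecar, kinds are inferred: float/int columns with exactly two
    distinct values in {0, 1} are binary, other numerics numeric, object
    columns categorical; the column literally named ``class`` (or the last
    column) is the label.
    """
    df = pd.read_csv(csv_path)
    if schema_path is not None:
        mapping = yaml.safe_load(Path(schema_path).read_text())
        schema = [ColumnSchema(name, kind) for name, kind in mapping.items()]
        label = [s.name for s in schema if s.kind == "label"][0]
    else:
        label = "class" if "class" in df.columns else df.columns[-1]
        schema = []
        for c in df.columns:
            if c == label:
                schema.append(ColumnSchema(c, "label"))
            elif df[c].dtype == object:
                schema.append(ColumnSchema(c, "categorical"))
            elif set(df[c].dropna().unique()) <= {0, 1}:
                schema.append(ColumnSchema(c, "binary"))
            else:
                schema.append(ColumnSchema(c, "numeric"))
    X = df[[s.name for s in schema if s.kind != "label"]]
    return TabularDataset(X, df[label], schema, {"source": str(csv_path)})


def save_csv(dataset: TabularDataset, csv_path: str | Path, schema_path: str | Path | None = None) -> None:
    label = [s for s in dataset.schema if s.kind == "label"][0]
    out = dataset.X.copy()
    out[label.name] = dataset.y.to_numpy()
    out.to_csv(csv_path, index=False)
    if schema_path is not None:
        mapping = {s.name: s.kind for s in dataset.schema}
        Path(schema_path).write_text(yaml.safe_dump(mapping, sort_keys=False))
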