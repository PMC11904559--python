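"""Tabular data ingestion and archetype-specific preprocessing.

A :class:`Dataset` is an N x M feature matrix plus labels and per-column
metadata. Columns are either numeric (floats), categorical (string codes,
expanded during preprocessing), signal-derived numeric features, or omics
numeric features. Preprocessing standardizes/encodes columns and, for
high-dimensional data, removes near-constant features by a variance floor.

Conventions: the population (divide-by-N) variance is used everywhere so a
single variance definition runs through scaling, filtering and the selector.
Constant numeric columns standardize to all-zeros rather than raising; the
variance filter, not the scaler, is what removes dead features. Missing
values are rejected, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

FeatureKind = Literal["numeric", "categorical", "signal", "omics"]

_NUMERIC_KINDS = ("numeric", "signal", "omics")


@dataclass(frozen=True)
class FeatureMeta:
    """Per-column metadata: display name, kind, and originating column."""

    name: str
    kind: FeatureKind = "numeric"
    original: Optional[str] = None

    def __post_init__(self):
        if self.original is None:
            object.__setattr__(self, "original", self.name)


@dataclass
class Dataset:
    """Feature matrix, labels, and column metadata.

    ``X`` holds floats once fully preprocessed; before categorical encoding
    it may be an object array carrying string codes in categorical columns.
    ``informative_mask`` is the synthetic ground truth (True for features
    that carry class signal), absent for real data.
    """

    X: np.ndarray
    y: np.ndarray
    feature_meta: list[FeatureMeta]
    informative_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise InputError("X must be a 2-D matrix")
        n, m = self.X.shape
        if len(self.y) != n:
            raise InputError(f"label length {len(self.y)} != row count {n}")
        if len(self.feature_meta) != m:
            raise InputError(
                f"feature_meta length {len(self.feature_meta)} != column count {m}"
            )
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape != (m,):
                raise InputError("informative_mask length must equal column count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y))

    @property
    def feature_names(self) -> list[str]:
        return [fm.name for fm in self.feature_meta]

    def numeric_matrix(self) -> np.ndarray:
        """The feature matrix as floats; raises if categorical codes remain."""
        try:
            return np.asarray(self.X, dtype=float)
        except (TypeError, ValueError) as exc:
            raise InputError(
                "dataset still contains unencoded categorical columns; "
                "run preprocess() first"
            ) from exc

    def subset(self, columns: Sequence[int]) -> "Dataset":
        """A view-copy restricted to the given column indices."""
        cols = list(columns)
        mask = None
        if self.informative_mask is not None:
            mask = self.informative_mask[cols]
        return Dataset(
            X=self.X[:, cols],
            y=self.y.copy(),
            feature_meta=[self.feature_meta[c] for c in cols],
            informative_mask=mask,
        )


@dataclass(frozen=True)
class PreprocessSpec:
    """How to normalize, encode and (for high-dimensional data) denoise.

    ``highdim_variance_floor`` drops features whose population variance falls
    below it; applied only under ``archetype='highdim'``.
    """

    numeric_mode: Literal["zscore", "minmax", "none"] = "zscore"
    categorical_mode: Literal["onehot", "ordinal"] = "onehot"
    highdim_variance_floor: float = 0.0
    archetype: Literal["numeric", "categorical_mixed", "signal", "highdim"] = "numeric"

    def __post_init__(self):
        if self.highdim_variance_floor < 0:
            raise ConfigurationError("highdim_variance_floor must be >= 0")
        if self.numeric_mode not in ("zscore", "minmax", "none"):
            raise ConfigurationError(f"unknown numeric_mode {self.numeric_mode!r}")
        if self.categorical_mode not in ("onehot", "ordinal"):
            raise ConfigurationError(
                f"unknown categorical_mode {self.categorical_mode!r}"
            )


def read_table(
    path: str | Path,
    label_column: str,
    delimiter: str = ",",
) -> Dataset:
    """Read a delimited text file with a header row into a :class:`Dataset`.

    Columns whose values all parse as numbers are typed numeric; any other
    column is typed categorical. Row order is preserved. Missing values are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, dtype=str,
                         skip_blank_lines=True, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise InputError(f"unparseable row in {path}: {exc}") from exc
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns are "
            f"{list(df.columns)}"
        )
    if df.shape[0] == 0:
        raise InputError(f"{path} contains no data rows")

    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if any(v == "" for v in row):
            raise InputError(f"missing value on line {line_no} of {path}")

    y_raw = df[label_column]
    y_num = pd.to_numeric(y_raw, errors="coerce")
    y = y_num.to_numpy() if not y_num.isna().any() else y_raw.to_numpy()

    feat_df = df.drop(columns=[label_column])
    columns: list[np.ndarray] = []
    meta: list[FeatureMeta] = []
    for name in feat_df.columns:
        col = feat_df[name]
        as_num = pd.to_numeric(col, errors="coerce")
        if not as_num.isna().any():
            columns.append(as_num.to_numpy(dtype=float))
            meta.append(FeatureMeta(name=name, kind="numeric"))
        else:
            columns.append(col.to_numpy(dtype=object))
            meta.append(FeatureMeta(name=name, kind="categorical"))
    if not columns:
        raise InputError(f"{path} has no feature columns besides the label")
    any_cat = any(fm.kind == "categorical" for fm in meta)
    X = np.column_stack(columns)
    if not any_cat:
        X = X.astype(float)
    return Dataset(X=X, y=y, feature_meta=meta)


def _population_variance(col: np.ndarray) -> float:
    return float(np.var(col))  # numpy default ddof=0: divide-by-N


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = np.sqrt(_population_variance(col))
    if sd == 0.0:
        return np.zeros_like(col, dtype=float)
    return (col - col.mean()) / sd


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros_like(col, dtype=float)
    return (col - lo) / (hi - lo)


def preprocess(ds: Dataset, spec: PreprocessSpec) -> Dataset:
    """Apply archetype-specific preprocessing, returning a new Dataset.

    Order of operations: categorical encoding, then (highdim only) the
    variance floor, then numeric scaling of every resulting column. The row
    count is never altered; the informative mask is propagated through
    derived columns (a dummy column is informative iff its parent is).
    """
    if ds.n_samples == 0 or ds.n_features == 0:
        raise InputError("cannot preprocess an empty dataset")

    columns: list[np.ndarray] = []
    meta: list[FeatureMeta] = []
    mask_parts: list[bool] = []
    src_mask = ds.informative_mask

    for j, fm in enumerate(ds.feature_meta):
        col = ds.X[:, j]
        informative = bool(src_mask[j]) if src_mask is not None else False
        if fm.kind == "categorical":
            values = np.asarray([str(v) for v in col], dtype=object)
            levels = sorted(set(values))
            if spec.categorical_mode == "onehot":
                for lv in levels:
                    columns.append((values == lv).astype(float))
                    meta.append(FeatureMeta(name=f"{fm.name}={lv}",
                                            kind="categorical",
                                            original=fm.original))
                    mask_parts.append(informative)
            else:  # ordinal: codes by sorted level order
                codes = {lv: float(i) for i, lv in enumerate(levels)}
                columns.append(np.asarray([codes[v] for v in values]))
                meta.append(replace(fm, name=fm.name))
                mask_parts.append(informative)
        else:
            num = np.asarray(col, dtype=float)
            if np.isnan(num).any():
                raise InputError(f"missing values in column {fm.name!r}")
            columns.append(num)
            meta.append(fm)
            mask_parts.append(informative)

    X = np.column_stack(columns)
    mask = np.asarray(mask_parts, dtype=bool)

    if spec.archetype == "highdim" and spec.highdim_variance_floor > 0:
        variances = np.var(X, axis=0)
        keep = variances >= spec.highdim_variance_floor
        if not keep.any():
            raise InputError("variance floor removed every feature")
        X = X[:, keep]
        meta = [m for m, k in zip(meta, keep) if k]
        mask = mask[keep]

    if spec.numeric_mode == "zscore":
        X = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
    elif spec.numeric_mode == "minmax":
        X = np.column_stack([_minmax(X[:, j]) for j in range(X.shape[1])])

    return Dataset(
        X=X.astype(float),
        y=ds.y.copy(),
        feature_meta=meta,
        informative_mask=mask if src_mask is not None else None,
    )


def write_dataset(
    ds: Dataset,
    path: str | Path,
    label_column: str = "label",
    delimiter: str = ",",
    sidecar: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Write a dataset to CSV plus a JSON sidecar with column metadata.

    Returns the (csv_path, sidecar_path) pair. The sidecar records column
    kinds, the informative mask if present, and any extra fields supplied.
    """
    path = Path(path)
    df = pd.DataFrame({fm.name: ds.X[:, j] for j, fm in enumerate(ds.feature_meta)})
    df[label_column] = ds.y
    df.to_csv(path, sep=delimiter, index=False)
    doc = {
        "label_column": label_column,
        "columns": [
            {"name": fm.name, "kind": fm.kind, "original": fm.original}
            for fm in ds.feature_meta
        ],
    }
    if ds.informative_mask is not None:
        doc["informative_mask"] = [bool(b) for b in ds.informative_mask]
    if sidecar:
        doc.update(sidecar)
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    sidecar_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path, sidecar_path


def read_sidecar(csv_path: str | Path) -> dict:
    """Load the JSON sidecar written next to a dataset CSV."""
    p = Path(csv_path)
    sidecar_path = p.with_suffix(p.suffix + ".meta.json")
    if not sidecar_path.exists():
        raise InputError(f"no sidecar found at {sidecar_path}")
    return json.loads(sidecar_path.read_text())
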