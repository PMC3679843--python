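"""Descriptor-table input/output and autoscaling pretreatment.

Molecular descriptors arrive precomputed as delimited text (rows = molecules,
columns = descriptors, first column = sample identifier, optional measured and
predicted response columns).  Autoscaling (per-descriptor centering and unit
variance scaling) is always fitted on training data only and then applied,
with the fitted statistics, to any query data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DescriptorTable",
    "ScalingParams",
    "AutoScaler",
    "read_descriptor_table",
    "write_descriptor_table",
    "autoscale_fit",
    "autoscale_apply",
    "autoscale_inverse",
]

_DELIMITERS = [",", ";", "\t"]


@dataclass
class DescriptorTable:
    """An identified set of samples with descriptor values and optional responses.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample labels, one per row of ``X``.
    X : ndarray of shape (n, p)
        Descriptor matrix; must be finite (missing values are a load error).
    descriptor_names : list of str
        Column labels for ``X``.
    y : ndarray of shape (n,), optional
        Measured response values.
    y_hat : ndarray of shape (n,), optional
        Predicted response values.
    """

    sample_ids: list[str]
    X: np.ndarray
    descriptor_names: list[str]
    y: np.ndarray | None = None
    y_hat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ValueError("descriptor table needs at least one sample and one descriptor")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        if len(self.descriptor_names) != p:
            raise ValueError("descriptor_names length does not match number of columns")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite descriptor value at sample {self.sample_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )
        for name in ("y", "y_hat"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def select(self, indices: Sequence[int]) -> "DescriptorTable":
        """Return a new table restricted to the given row indices (in order)."""
        idx = np.asarray(indices, dtype=int)
        return DescriptorTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            X=self.X[idx],
            descriptor_names=list(self.descriptor_names),
            y=None if self.y is None else self.y[idx],
            y_hat=None if self.y_hat is None else self.y_hat[idx],
        )

    def to_dataframe(self, id_column: str = "sample_id") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, id_column, self.sample_ids)
        if self.y is not None:
            df["y"] = self.y
        if self.y_hat is not None:
            df["y_hat"] = self.y_hat
        return df


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_descriptor_table(
    path: str | Path,
    id_column: str | None = None,
    response_column: str | None = None,
    prediction_column: str | None = None,
    delimiter: str | None = None,
) -> DescriptorTable:
    """Read a delimited-text descriptor table.

    All columns other than the identifier, response and prediction columns are
    taken as descriptors, in file order.  The delimiter is auto-detected among
    comma, semicolon and tab unless given; decimal points are required
    (no locale decimal commas).

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        On duplicate ids, non-numeric or missing descriptor cells (the error
        names the offending sample and column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such descriptor file: {path}")
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    if raw.shape[1] < 2:
        raise ValueError("descriptor file must have an id column and at least one descriptor")
    if id_column is None:
        id_column = raw.columns[0]
    for col in (id_column, response_column, prediction_column):
        if col is not None and col not in raw.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    ids = raw[id_column].tolist()
    dupes = _duplicates(ids)
    if dupes:
        raise ValueError(f"duplicate sample ids in {path.name}: {sorted(dupes)}")

    special = {id_column, response_column, prediction_column} - {None}
    desc_cols = [c for c in raw.columns if c not in special]

    def _numeric(col: str, required: bool = True) -> np.ndarray:
        vals = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                raise ValueError(
                    f"missing value at sample {ids[i]!r}, column {col!r} in {path.name}"
                )
            try:
                vals[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at sample {ids[i]!r}, "
                    f"column {col!r} in {path.name}"
                ) from None
        return vals

    X = np.column_stack([_numeric(c) for c in desc_cols])
    y = _numeric(response_column) if response_column else None
    y_hat = _numeric(prediction_column) if prediction_column else None
    return DescriptorTable(ids, X, desc_cols, y=y, y_hat=y_hat)


def write_descriptor_table(
    table: DescriptorTable,
    path: str | Path,
    id_column: str = "sample_id",
    response_column: str = "y",
    prediction_column: str = "y_hat",
    delimiter: str = ",",
) -> None:
    """Write a table as delimited text at full round-trip precision."""
    df = pd.DataFrame(
        {id_column: table.sample_ids}
        | {name: table.X[:, j] for j, name in enumerate(table.descriptor_names)}
    )
    if table.y is not None:
        df[response_column] = table.y
    if table.y_hat is not None:
        df[prediction_column] = table.y_hat
    df.to_csv(path, sep=delimiter, index=False, quoting=csv.QUOTE_MINIMAL)


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingParams:
    """Per-descriptor mean and standard deviation (n−1 denominator).

    ``kept_columns`` records the original column indices retained when
    constant descriptors were dropped at fit time; ``None`` means all.
    """

    means: np.ndarray
    sds: np.ndarray
    kept_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise ValueError("means and sds must be 1-D of equal length")
        if np.any(self.sds <= 0):
            raise ValueError("all scaling standard deviations must be strictly positive")

    @property
    def p(self) -> int:
        return self.means.shape[0]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, DescriptorTable):
        return data.X
    return np.asarray(data, dtype=float)


def autoscale_fit(train, drop_constant: bool = False, names: Sequence[str] | None = None) -> ScalingParams:
    """Fit autoscaling statistics on training data only.

    Standard deviations use the n−1 denominator.  Zero-variance descriptors
    are a hard error unless ``drop_constant`` is set, in which case they are
    removed and the retained column indices recorded.
    """
    X = _as_matrix(train)
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least two training samples")
    if names is None:
        names = (
            train.descriptor_names
            if isinstance(train, DescriptorTable)
            else [f"x{j}" for j in range(X.shape[1])]
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sds == 0)
    if const.size:
        if not drop_constant:
            bad = [names[j] for j in const]
            raise ValueError(f"zero-variance descriptors (constant in training data): {bad}")
        keep = np.flatnonzero(sds > 0)
        if keep.size == 0:
            raise ValueError("all descriptors are constant; nothing left to scale")
        return ScalingParams(means[keep], sds[keep], kept_columns=keep)
    return ScalingParams(means, sds)


def autoscale_apply(X, params: ScalingParams) -> np.ndarray:
    """Apply fitted scaling: (x − mean) / sd per column."""
    X = _as_matrix(X)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != params.p:
        if params.kept_columns is not None and X.shape[1] > params.kept_columns.max():
            X = X[:, params.kept_columns]
        else:
            raise ValueError(
                f"dimension mismatch: data has {X.shape[1]} columns, scaling expects {params.p}"
            )
    return (X - params.means) / params.sds


def autoscale_inverse(X_scaled, params: ScalingParams) -> np.ndarray:
    """Invert autoscaling: x·sd + mean per column."""
    X_scaled = np.asarray(X_scaled, dtype=float)
    if X_scaled.shape[-1] != params.p:
        raise ValueError("dimension mismatch in autoscale_inverse")
    return X_scaled * params.sds + params.means


class AutoScaler(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapping :func:`autoscale_fit` / :func:`autoscale_apply`.

    Differs from ``StandardScaler`` in using the n−1 denominator conventional
    in chemometrics, and in treating zero-variance descriptors as an error
    unless ``drop_constant`` is set.
    """

    def __init__(self, drop_constant: bool = False):
        self.drop_constant = drop_constant

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        self.params_ = autoscale_fit(X, drop_constant=self.drop_constant)
        return self

    def transform(self, X):
        return autoscale_apply(X, self.params_)

    def inverse_transform(self, X):
        return autoscale_inverse(X, self.params_)
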