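"""Labeled square matrices exchanged between pipeline stages.

Three light wrappers around a pandas DataFrame keep the semantics of each
matrix explicit: :class:`DirectionalMatrix` for directed quantities (TSIB
hours, relative dispersal probabilities, migration rates),
:class:`ConnectivityMatrix` for the OC network statistic, and
:class:`DiffMatrix` for symmetric genetic differentiation.  All serialize to
labeled CSV; metadata travels in a JSON sidecar (``<file>.meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _as_square_frame(values, labels=None) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        df = values.copy()
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
    else:
        arr = np.asarray(values, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        df = pd.DataFrame(arr, index=[str(x) for x in labels], columns=[str(x) for x in labels])
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError("matrix must be square with matching row/column labels")
    if df.values.dtype.kind not in "fi" or np.isnan(df.values).any():
        raise ValueError("matrix must be numeric with no NaN")
    return df.astype(float)


def _write_labeled(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    path = Path(path)
    df.to_csv(path, index_label="population")
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def _read_labeled(path: str | Path):
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    side = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return df, meta


@dataclass
class DirectionalMatrix:
    """Directed population-by-population quantity.

    ``kind`` tags the semantics: ``"tsib_hours"`` (summed residence time),
    ``"rel_prob"`` (relative dispersal probability), ``"oc"`` or
    ``"migration"``.  ``symmetric`` marks matrices built by per-pair
    summation; the diagonal (self-retention) is stored but excluded from all
    pair-level normalization downstream.
    """

    values: pd.DataFrame
    kind: str = "tsib_hours"
    symmetric: bool = False

    def __post_init__(self):
        self.values = _as_square_frame(self.values)
        if (self.values.values < 0).any() and self.kind != "migration_residual":
            raise ValueError("directional matrices must be non-negative")
        if self.symmetric and not np.allclose(self.values.values, self.values.values.T):
            raise ValueError("matrix flagged symmetric but values differ from transpose")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def off_diagonal(self) -> np.ndarray:
        """All n(n-1) off-diagonal entries, row-major fixed order."""
        a = self.values.values
        return a[~np.eye(a.shape[0], dtype=bool)]

    def to_csv(self, path) -> None:
        _write_labeled(self.values, path, {"kind": self.kind, "symmetric": self.symmetric})

    @classmethod
    def from_csv(cls, path) -> "DirectionalMatrix":
        df, meta = _read_labeled(path)
        return cls(df, kind=meta.get("kind", "tsib_hours"), symmetric=meta.get("symmetric", False))


@dataclass
class ConnectivityMatrix:
    """Oceanic connectivity (OC): shortest-path relative dispersal probability.

    ``mode`` is ``"symmetric"`` (OC_S) or ``"asymmetric"`` (OC_A);
    ``transformed`` records whether the square-root normality transform has
    been applied.  Metadata about the normalization and the path-divisor
    convention is carried for provenance.
    """

    values: pd.DataFrame
    mode: str
    transformed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = _as_square_frame(self.values)
        v = self.values.values
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValueError("OC values must lie in [0, 1]")
        if self.mode not in ("symmetric", "asymmetric"):
            raise ValueError("mode must be 'symmetric' or 'asymmetric'")
        if self.mode == "symmetric" and not np.array_equal(v, v.T):
            raise ValueError("symmetric-mode OC must equal its transpose exactly")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def sqrt(self) -> "ConnectivityMatrix":
        """Square-root transform (for normality); idempotence is guarded."""
        if self.transformed:
            return self
        return ConnectivityMatrix(pd.DataFrame(np.sqrt(self.values.values),
                                               index=self.values.index,
                                               columns=self.values.columns),
                                  self.mode, True, {**self.meta, "transform": "sqrt"})

    def to_csv(self, path) -> None:
        _write_labeled(self.values, path,
                       {"mode": self.mode, "transformed": self.transformed, **self.meta})

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df, meta = _read_labeled(path)
        mode = meta.pop("mode", "symmetric")
        transformed = meta.pop("transformed", False)
        return cls(df, mode=mode, transformed=transformed, meta=meta)


@dataclass
class DiffMatrix:
    """Symmetric pairwise genetic differentiation for one metric.

    ``metric`` is one of GST, GpST, JostD, RST.  Estimates may be slightly
    negative in undifferentiated data; raw values are stored (``clamped()``
    gives the zero-floored view) and ``linearized`` marks the x/(1-x)
    transform.
    """

    values: pd.DataFrame
    metric: str
    linearized: bool = False

    METRICS = ("GST", "GpST", "JostD", "RST")

    def __post_init__(self):
        self.values = _as_square_frame(self.values)
        if self.metric not in self.METRICS:
            raise ValueError(f"metric must be one of {self.METRICS}")
        v = self.values.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("differentiation matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("differentiation matrix must have zero diagonal")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def clamped(self) -> pd.DataFrame:
        return self.values.clip(lower=0.0)

    def to_csv(self, path) -> None:
        _write_labeled(self.values, path, {"metric": self.metric, "linearized": self.linearized})

    @classmethod
    def from_csv(cls, path) -> "DiffMatrix":
        df, meta = _read_labeled(path)
        return cls(df, metric=meta.get("metric", "GST"), linearized=meta.get("linearized", False))
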