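"""Reading and writing the package's tabular formats.

Feature matrices, labels, dissimilarity matrices and embeddings are all plain
delimited text (TSV by default): one row per sample, first column the sample
identifier, header row carrying feature / column names.  In memory a feature
matrix is a :class:`pandas.DataFrame` with the sample identifiers as index and
the feature identifiers as columns; labels are a :class:`pandas.Series`
indexed by sample identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "read_feature_matrix",
    "read_labels",
    "read_dissimilarity",
    "write_dissimilarity",
    "pair_on_shared_samples",
    "write_embedding",
    "read_embedding",
    "load_config",
]


@dataclass
class RunConfig:
    """Hyperparameters of an alignment run.

    Attributes
    ----------
    dim : embedding dimensionality d.
    matching_penalty : weight λ of the cross-domain coupling term.
    epsilon : entropic regularization ε of the transport problem.
    knn : neighbourhood size k of the geodesic-distance graph.
    dissimilarity : ``"geodesic"`` or ``"euclidean"``.
    max_outer : cap on outer alternations.
    tol_P : relative Frobenius change of the plan P that stops the alternation.
    seed : base random seed.
    n_runs : number of repeated runs for mean ± sd reporting.
    """

    dim: int = 2
    matching_penalty: float = 1.0
    epsilon: float = 0.01
    knn: int = 10
    dissimilarity: str = "geodesic"
    max_outer: int = 100
    tol_P: float = 1e-5
    seed: int = 0
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.matching_penalty < 0:
            raise ValueError("matching_penalty must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.dissimilarity not in ("geodesic", "euclidean"):
            raise ValueError(f"unknown dissimilarity mode {self.dissimilarity!r}")


def _check_feature_frame(df: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    where = f" in {path}" if path is not None else ""
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs{where}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs{where}: {dupes}")
    if len(df) < 2:
        raise ValueError(f"need at least 2 samples{where}, got {len(df)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any() or df[col].isna().any():
                row = df.index[(coerced.isna()).to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric or missing value{where} at sample {row!r}, feature {col!r}"
                )
        raise ValueError(f"non-numeric data{where}")
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite or missing value{where} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r}"
        )
    return df.astype(float)


def read_feature_matrix(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a samples × features table; first column = sample ID, header = feature IDs.

    Missing or non-numeric cells are rejected (the alignment pipelines assume
    complete matrices); the error names the offending sample and feature.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, keep_default_na=True)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return _check_feature_frame(df, path)


def read_labels(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, label) table into a Series."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"label file {path} must have exactly two columns")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in label file {path}")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    return s


def read_dissimilarity(path: str | Path, delimiter: str = "\t") -> np.ndarray:
    """Read a square dissimilarity matrix (IDs in first column and header)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    D = df.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError(f"dissimilarity matrix in {path} is not square: {D.shape}")
    return D


def write_dissimilarity(
    D: np.ndarray, ids: Sequence[str], path: str | Path, delimiter: str = "\t"
) -> None:
    if len(ids) != D.shape[0]:
        raise ValueError("number of IDs does not match matrix size")
    pd.DataFrame(D, index=list(ids), columns=list(ids)).to_csv(path, sep=delimiter)


def pair_on_shared_samples(
    A: pd.DataFrame, B: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two feature matrices to their shared samples, in one canonical order.

    Rows are sorted lexicographically by sample ID so that row i of both
    outputs refers to the same sample — the true match used by FOSCTTM.
    """
    shared = sorted(set(A.index) & set(B.index))
    if not shared:
        raise ValueError("no shared sample IDs between the two matrices")
    return A.loc[shared], B.loc[shared]


def write_embedding(
    Z: np.ndarray, ids: Sequence[str], domain_tag: str, path: str | Path
) -> None:
    """Write an n × d embedding as TSV with columns sample_id, domain, dim_1..dim_d."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("embedding must be 2-dimensional")
    if len(ids) != Z.shape[0]:
        raise ValueError(f"{len(ids)} IDs for {Z.shape[0]} embedding rows")
    df = pd.DataFrame(Z, columns=[f"dim_{j + 1}" for j in range(Z.shape[1])])
    df.insert(0, "domain", domain_tag)
    df.insert(0, "sample_id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_embedding(path: str | Path) -> tuple[np.ndarray, list[str], str]:
    """Read an embedding written by :func:`write_embedding`.

    Returns (coordinates, sample IDs, domain tag).
    """
    df = pd.read_csv(path, sep="\t")
    dims = [c for c in df.columns if c.startswith("dim_")]
    tags = df["domain"].unique()
    if len(tags) != 1:
        raise ValueError(f"embedding file {path} mixes domain tags {tags}")
    return df[dims].to_numpy(dtype=float), df["sample_id"].astype(str).tolist(), str(tags[0])


_CONFIG_KEYS = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Overrides (e.g. CLI flags) take precedence over file values; ``None``
    overrides are ignored.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
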