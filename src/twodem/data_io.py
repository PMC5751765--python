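"""Reading and writing expression matrices, label vectors and feature-matrix exports.

Input tables are delimited text (TSV or CSV, decided by file extension) with
one header row and a leading identifier column.  The dominant distribution
convention for transcriptome matrices — rows are genes/CpGs, columns are
samples — is the default orientation; an explicit flag overrides it.  Missing
or non-finite cells are rejected rather than imputed, because silent
imputation would change downstream clustering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "read_matrix",
    "read_labels",
    "write_labels",
    "export_feature_matrix",
]

# 17 significant digits round-trip any IEEE double exactly
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ExpressionMatrix:
    """An n-sample x d-feature numeric table with unique identifiers.

    Values are unitless pre-processed intensities (microarray expression,
    methylation Beta- or M-values); no normalization is applied here.
    """

    values: np.ndarray  # shape (n, d), float64
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = v.shape
        if n < 2 or d < 1:
            raise ValueError(f"need n >= 2 samples and d >= 1 features, got n={n}, d={d}")
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValueError("identifier lists do not match matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.isfinite(v).all():
            i, j = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabelVector:
    """Integer cluster assignments in {0, ..., c-1} for named samples."""

    labels: np.ndarray  # shape (n,), int
    c: int
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if lab.size and (lab.min() < 0 or lab.max() >= self.c):
            raise ValueError(f"labels must lie in [0, {self.c - 1}]")
        if self.sample_ids is not None:
            if len(self.sample_ids) != lab.size:
                raise ValueError("sample_ids length does not match labels")
            _check_unique(self.sample_ids, "sample")

    def __len__(self) -> int:
        return int(self.labels.size)


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} ID {x!r}")
        seen.add(x)


def _sep_for(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_matrix(path, orientation: str = "features_in_rows") -> ExpressionMatrix:
    """Load a delimited expression table into samples x features orientation.

    Parameters
    ----------
    path
        TSV/CSV file with one header row and a leading ID column.
    orientation
        ``"features_in_rows"`` (default: rows are features, columns are
        samples) or ``"samples_in_rows"``.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    # pandas silently renames duplicate header fields, so check them raw
    col_kind, row_kind = (
        ("sample", "feature") if orientation == "features_in_rows" else ("feature", "sample")
    )
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, col_kind)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate {row_kind} ID {dup!r} in {path}")
    if orientation == "features_in_rows":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"missing or non-finite value at sample {sample_ids[i]!r}, "
            f"feature {feature_ids[j]!r} in {path}"
        )
    return ExpressionMatrix(values, sample_ids, feature_ids)


def write_matrix(E: ExpressionMatrix, path, orientation: str = "features_in_rows") -> None:
    """Write an expression matrix as delimited text (lossless round-trip)."""
    df = pd.DataFrame(E.values, index=E.sample_ids, columns=E.feature_ids)
    if orientation == "features_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)


def read_labels(path, matrix: ExpressionMatrix | None = None) -> LabelVector:
    """Read a two-column (sample_id, label) table.

    Labels must be non-negative integer tokens; ``c`` is inferred as
    ``max(label) + 1``.  If ``matrix`` is given, every sample ID must occur
    in it.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, label), got {df.shape[1]}")
    ids = [str(s) for s in df.iloc[:, 0]]
    labels = []
    for sid, tok in zip(ids, df.iloc[:, 1]):
        try:
            labels.append(int(str(tok)))
        except ValueError:
            raise ValueError(f"{path}: non-integer label {tok!r} for sample {sid!r}") from None
    lab = np.array(labels, dtype=int)
    if lab.size and lab.min() < 0:
        raise ValueError(f"{path}: negative label")
    if matrix is not None:
        unknown = sorted(set(ids) - set(matrix.sample_ids))
        if unknown:
            raise ValueError(f"{path}: sample IDs not in matrix: {unknown}")
    c = int(lab.max()) + 1 if lab.size else 1
    return LabelVector(lab, c, sample_ids=ids)


def write_labels(lv: LabelVector, path) -> None:
    """Write labels as two-column delimited text (sample_id, cluster)."""
    ids = lv.sample_ids
    if ids is None:
        ids = [f"S{i}" for i in range(len(lv))]
    with open(path, "w") as fh:
        sep = _sep_for(path)
        for sid, lab in zip(ids, lv.labels):
            fh.write(f"{sid}{sep}{int(lab)}\n")


def export_feature_matrix(X: np.ndarray, path, heatmap: bool = False) -> None:
    """Write one folded sample (an m x q feature matrix) as a TSV grid.

    Two exported samples can be compared visually side by side, the matrix
    layout making group-specific intensity patterns apparent.  With
    ``heatmap=True`` a PNG heat map is written next to the text file.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("feature matrix must be a non-empty 2-D array")
    np.savetxt(path, X, delimiter="\t", fmt=_FLOAT_FMT)
    if heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        im = ax.imshow(X, cmap="viridis")
        fig.colorbar(im, ax=ax)
        fig.savefig(os.path.splitext(str(path))[0] + ".png", dpi=100)
        plt.close(fig)
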