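"""Reading and writing expression matrices and feature-selection tables.

The on-disk format is the CuMiDa-style delimited table: one row per sample,
a sample-id column first, a categorical class column (named ``type`` in
CuMiDa's distribution), and one numeric column per gene probe.  The loader
validates structure hard by default — a blank or non-numeric expression cell
is an error naming the offending row and column, because silent coercion of
intensity values is how label leakage and NaN propagation start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataParseError, StructuralError

__all__ = [
    "ClassMap",
    "ExpressionMatrix",
    "GSE9476_CLASS_MAP",
    "read_expression",
    "write_expression",
    "write_selection",
    "read_selection",
]


@dataclass(frozen=True)
class ClassMap:
    """Ordered bijection from class name to integer code 1..c."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise StructuralError("a class map needs at least 2 classes")
        if len(set(self.names)) != len(self.names):
            raise StructuralError("class names must be unique")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "ClassMap":
        """Build a map from first-appearance order of the labels."""
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(str(lab))
        return cls(tuple(seen))

    @property
    def n_classes(self) -> int:
        return len(self.names)

    def code(self, name: str) -> int:
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise StructuralError(f"label {name!r} not in class map {self.names}") from None

    def codes(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.code(str(lab)) for lab in labels], dtype=np.int64)

    def as_dict(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.names)}


#: Class order used by the leukemia study dataset (GSE9476): codes 1..5.
GSE9476_CLASS_MAP = ClassMap(
    ("Bone_Marrow_CD34", "Bone_Marrow", "AML", "PB", "PBSC_CD34")
)


@dataclass
class ExpressionMatrix:
    """A samples-by-genes expression matrix with per-sample class labels.

    ``values[i, j]`` is the intensity of gene ``gene_ids[j]`` in sample
    ``sample_ids[i]``; ``labels[i]`` is that sample's class name.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray
    class_map: ClassMap = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray([str(x) for x in self.labels], dtype=object)
        if self.values.ndim != 2:
            raise StructuralError("values must be a 2-D samples x genes matrix")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise StructuralError(f"need n >= 2 samples and m >= 1 genes, got {n}x{m}")
        if len(self.sample_ids) != n:
            raise StructuralError("sample_ids length does not match row count")
        if len(self.gene_ids) != m:
            raise StructuralError("gene_ids length does not match column count")
        if len(set(self.gene_ids)) != m:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise StructuralError(f"duplicate gene ids: {dupes[:5]}")
        if self.labels.shape[0] != n:
            raise StructuralError("labels length does not match sample count")
        if np.isnan(self.values).any():
            i, j = map(int, np.argwhere(np.isnan(self.values))[0])
            raise DataParseError(
                f"missing expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.class_map is None:
            self.class_map = ClassMap.from_labels(self.labels)
        for lab in self.labels:
            self.class_map.code(lab)  # raises if a label is outside the map

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def label_codes(self) -> np.ndarray:
        """Integer class codes 1..c, aligned with rows."""
        return self.class_map.codes(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == name)) for name in self.class_map.names
        }

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return ExpressionMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=self.labels[idx],
            class_map=self.class_map,
        )

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return ExpressionMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=self.labels,
            class_map=self.class_map,
        )

    def to_dataframe(self, label_column: str = "type") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_ids)
        df.insert(0, label_column, self.labels)
        df.insert(0, "samples", self.sample_ids)
        return df


def read_expression(
    path: str | Path,
    label_column: str = "type",
    class_map: ClassMap | None = None,
    sep: str = ",",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a CuMiDa-style delimited expression table.

    First column = sample id, ``label_column`` = class label, every remaining
    column = one gene probe.  Row and column order are preserved.  Missing or
    non-numeric expression cells are rejected unless ``impute_missing`` is
    set, in which case blanks are replaced by the gene's mean over observed
    samples (non-numeric text is always an error).
    """
    path = Path(path)
    # pandas silently renames duplicate header fields, so check the raw header
    import csv as _csv

    with open(path, newline="") as fh:
        header = next(_csv.reader(fh, delimiter=sep))
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise StructuralError(f"{path}: duplicate gene ids in header: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 3:
        raise StructuralError(
            f"{path}: need sample-id, label and at least one gene column"
        )
    if label_column not in df.columns:
        raise StructuralError(f"{path}: label column {label_column!r} not found")

    sample_col = df.columns[0]
    if sample_col == label_column:
        raise StructuralError(f"{path}: first column cannot be the label column")
    sample_ids = [str(s) for s in df[sample_col]]
    labels = df[label_column].astype(str).to_numpy(dtype=object)
    gene_cols = [c for c in df.columns if c not in (sample_col, label_column)]

    raw = df[gene_cols]
    try:
        # numpy's string->float conversion round-trips exactly, unlike the
        # fast parser behind pd.to_numeric
        values = raw.to_numpy(dtype=np.float64, na_value=np.nan)
    except (ValueError, TypeError):
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = (numeric.isna() & raw.notna()).to_numpy()
        i, j = np.argwhere(bad)[0]
        raise DataParseError(
            f"{path}: non-numeric expression value {raw.iat[i, j]!r} at sample "
            f"{sample_ids[i]!r}, gene {gene_cols[j]!r}"
        ) from None
    if np.isnan(values).any():
        if impute_missing:
            col_means = np.nanmean(values, axis=0)
            holes = np.argwhere(np.isnan(values))
            values[holes[:, 0], holes[:, 1]] = col_means[holes[:, 1]]
        else:
            i, j = map(int, np.argwhere(np.isnan(values))[0])
            raise DataParseError(
                f"{path}: missing expression value at sample {sample_ids[i]!r}, "
                f"gene {gene_cols[j]!r}"
            )

    return ExpressionMatrix(
        values=values,
        sample_ids=sample_ids,
        gene_ids=gene_cols,
        labels=labels,
        class_map=class_map,
    )


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    label_column: str = "type",
    sep: str = ",",
) -> None:
    """Write a matrix back to the CuMiDa-style layout; round-trips with
    :func:`read_expression` to full float precision."""
    df = matrix.to_dataframe(label_column=label_column)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_selection(result, path: str | Path, index_base: int = 0) -> None:
    """Write a ranked feature-selection table: rank, gene index, gene id, score.

    ``index_base`` shifts printed gene indices (0 internal; 1 for reports that
    follow 1-based conventions).  Scores are printed with full precision so a
    read-back is numerically identical.
    """
    if len(result.selected) == 0:
        raise StructuralError("refusing to write an empty selection")
    gene_ids = result.gene_ids
    rows = []
    for rank, gi in enumerate(result.selected, start=1):
        rows.append(
            {
                "rank": rank,
                "gene_index": int(gi) + index_base,
                "gene_id": gene_ids[gi] if gene_ids is not None else str(gi),
                "score": result.scores[gi],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_selection(path: str | Path, index_base: int = 0) -> pd.DataFrame:
    """Read a table written by :func:`write_selection`; indices returned 0-based."""
    df = pd.read_csv(path)
    for col in ("rank", "gene_index", "gene_id", "score"):
        if col not in df.columns:
            raise StructuralError(f"{path}: selection table missing column {col!r}")
    df = df.copy()
    df["gene_index"] = df["gene_index"].astype(int) - index_base
    return df
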