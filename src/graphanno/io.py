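"""Readers and writers for the single-cell formats the pipeline touches.

Matrices are stored cells x features internally, regardless of on-disk
orientation (10x-style MTX files are features x cells and are transposed
on ingest).  Cell identifiers, not positions, are the join key between
matrices and label tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FeatureMatrix",
    "LabelTable",
    "PeakTable",
    "GeneTable",
    "FormatError",
    "ValidationError",
    "read_matrix",
    "read_labels",
    "read_bed",
    "read_genes",
    "write_predictions",
    "read_predictions",
    "write_embedding",
    "read_embedding",
]

MODALITIES = ("rna", "atac", "gene_activity")


class FormatError(ValueError):
    """Malformed input file (bad header, dimension mismatch, bad row)."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(list(ids)).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class FeatureMatrix:
    """Sparse (or dense) cells x features count/value matrix with identifiers.

    Parameters
    ----------
    values
        ``(n_cells, n_features)`` array or scipy sparse matrix; finite,
        and non-negative when it holds raw counts.
    cell_ids, feature_ids
        Unique string identifiers matching the matrix dimensions.
    modality
        One of ``rna``, ``atac``, ``gene_activity``.
    """

    values: sp.spmatrix | np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality {self.modality!r} not in {MODALITIES}"
            )
        n, f = self.values.shape
        if n != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if f != len(self.feature_ids):
            raise FormatError(
                f"matrix has {f} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.feature_ids, "feature ids")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValidationError("matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return the values as a dense float array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Column-subset (and reorder) to the given feature ids."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        vals = self.values.tocsc()[:, cols] if sp.issparse(self.values) else self.values[:, cols]
        return FeatureMatrix(vals, list(self.cell_ids), list(feature_ids), self.modality)

    def subset_cells(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = list(rows)
        vals = self.values.tocsr()[rows] if sp.issparse(self.values) else self.values[rows]
        return FeatureMatrix(
            vals, [self.cell_ids[i] for i in rows], list(self.feature_ids), self.modality
        )


@dataclass
class LabelTable:
    """Per-cell label assignment over a finite vocabulary (>= 2 labels)."""

    cell_ids: list[str]
    labels: list[str]
    vocabulary: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels length mismatch")
        if len(self.labels) == 0:
            raise ValidationError("empty label table")
        _check_unique(self.cell_ids, "cell ids in label table")
        if self.vocabulary is None:
            self.vocabulary = sorted(set(self.labels))
        else:
            unknown = set(self.labels) - set(self.vocabulary)
            if unknown:
                raise ValidationError(f"labels outside vocabulary: {sorted(unknown)[:5]}")
        if len(self.vocabulary) < 2:
            raise ValidationError("label vocabulary must contain at least 2 labels")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_indices(self, cell_order: Sequence[str]) -> np.ndarray:
        """Integer label codes (into ``vocabulary``) for cells in given order."""
        lut = dict(zip(self.cell_ids, self.labels))
        missing = [c for c in cell_order if c not in lut]
        if missing:
            raise ValidationError(f"cells without label: {missing[:5]}")
        vocab_index = {v: i for i, v in enumerate(self.vocabulary)}
        return np.array([vocab_index[lut[c]] for c in cell_order], dtype=int)

    def one_hot(self, cell_order: Sequence[str]) -> np.ndarray:
        """(n_cells, k) one-hot matrix in ``vocabulary`` order."""
        idx = self.to_indices(cell_order)
        out = np.zeros((len(idx), len(self.vocabulary)))
        out[np.arange(len(idx)), idx] = 1.0
        return out


@dataclass
class PeakTable:
    """Peak coordinates: 0-based half-open intervals keyed by peak id."""

    chrom: list[str]
    start: np.ndarray
    end: np.ndarray
    peak_ids: list[str]

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=int)
        self.end = np.asarray(self.end, dtype=int)
        n = len(self.peak_ids)
        if not (len(self.chrom) == len(self.start) == len(self.end) == n):
            raise ValidationError("peak table column length mismatch")
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValidationError(f"peak {self.peak_ids[bad]} has start >= end")
        _check_unique(self.peak_ids, "peak ids")

    def __len__(self) -> int:
        return len(self.peak_ids)


@dataclass
class GeneTable:
    """Gene coordinates with strand; 0-based half-open internally."""

    gene_ids: list[str]
    chrom: list[str]
    start: np.ndarray
    end: np.ndarray
    strand: list[str]

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=int)
        self.end = np.asarray(self.end, dtype=int)
        n = len(self.gene_ids)
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.strand) == n):
            raise ValidationError("gene table column length mismatch")
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValidationError(f"gene {self.gene_ids[bad]} has start >= end")
        bad_strand = set(self.strand) - {"+", "-"}
        if bad_strand:
            raise ValidationError(f"strand must be + or -, got {sorted(bad_strand)}")
        _check_unique(self.gene_ids, "gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# readers


def read_matrix(
    path: str,
    modality: str,
    barcodes: str | None = None,
    features: str | None = None,
    features_as_rows: bool | None = None,
) -> FeatureMatrix:
    """Read a count matrix from MTX + sidecars or a dense TSV.

    For MTX input, ``barcodes`` and ``features`` default to files named
    ``barcodes.tsv`` / ``features.tsv`` next to the matrix.  MTX files are
    assumed features x cells (10x layout) unless ``features_as_rows=False``;
    dense TSV is assumed cells x features with a header row of feature ids
    and the first column holding cell ids.
    """
    if path.endswith(".mtx"):
        directory = os.path.dirname(path)
        barcodes = barcodes or os.path.join(directory, "barcodes.tsv")
        features = features or os.path.join(directory, "features.tsv")
        try:
            mat = scipy.io.mmread(path).tocsr()
        except Exception as exc:  # mmread raises bare ValueError on bad headers
            raise FormatError(f"cannot parse MTX file {path}: {exc}") from exc
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        feat_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
        if features_as_rows is None:
            features_as_rows = True
        if features_as_rows:
            mat = mat.T.tocsr()
        n, f = mat.shape
        if n != len(cell_ids):
            raise FormatError(
                f"MTX declares {n} cells but barcodes file has {len(cell_ids)} rows"
            )
        if f != len(feat_ids):
            raise FormatError(
                f"MTX declares {f} features but features file has {len(feat_ids)} rows"
            )
        return FeatureMatrix(mat, cell_ids, feat_ids, modality)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = sp.csr_matrix(df.to_numpy(dtype=float))
    return FeatureMatrix(values, df.index.astype(str).tolist(), df.columns.astype(str).tolist(), modality)


def read_labels(path: str) -> LabelTable:
    """Read a 2-column (cell_id, label) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs >= 2 columns")
    df = df.dropna()
    return LabelTable(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def read_bed(path: str) -> PeakTable:
    """Read BED3+name peak intervals (0-based half-open, as BED defines)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ValidationError(f"{path}: no peaks")
    chrom, start, end, ids = zip(*rows)
    return PeakTable(list(chrom), np.array(start), np.array(end), list(ids))


def read_genes(path: str, dialect: str = "tsv") -> GeneTable:
    """Read a gene annotation table.

    ``dialect='tsv'``: header columns gene_id, chrom, start, end, strand with
    0-based half-open coordinates.  ``dialect='gtf'``: 1-based closed GTF-style
    coordinates in the same column layout, converted on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    start = df["start"].to_numpy(dtype=int)
    end = df["end"].to_numpy(dtype=int)
    if dialect == "gtf":
        start = start - 1  # 1-based closed -> 0-based half-open
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    return GeneTable(
        df["gene_id"].tolist(), df["chrom"].tolist(), start, end, df["strand"].tolist()
    )


# ---------------------------------------------------------------------------
# writers


def write_predictions(
    path: str,
    cell_ids: Sequence[str],
    labels: Sequence[str],
    probabilities: Sequence[float],
    flags: Sequence[str],
) -> None:
    """Write one row per target cell: id, predicted label, max probability, flag."""
    n = len(cell_ids)
    if not (len(labels) == len(probabilities) == len(flags) == n):
        raise ValidationError("prediction columns have unequal lengths")
    bad = set(flags) - {"confident", "ambiguous"}
    if bad:
        raise ValidationError(f"flags must be confident|ambiguous, got {sorted(bad)}")
    pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "predicted_label": list(labels),
            "max_probability": list(probabilities),
            "flag": list(flags),
        }
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "predicted_label": str})


def write_embedding(path: str, coords: np.ndarray, cell_ids: Sequence[str]) -> None:
    """Write an embedding as TSV (cells x dims) with full float precision."""
    if len(cell_ids) != coords.shape[0]:
        raise ValidationError("embedding rows and cell ids length mismatch")
    df = pd.DataFrame(
        coords, index=list(cell_ids), columns=[f"dim_{i}" for i in range(coords.shape[1])]
    )
    df.to_csv(path, sep="\t")  # default shortest-repr floats round-trip exactly


def read_embedding(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), df.index.astype(str).tolist()
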