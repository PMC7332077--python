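"""Per-gene annotation matrices and their preprocessing.

Three matrices enter the model for every gene:

* ``V`` (directed): real-valued, signed predicted allelic effects of each SNP on
  each epigenetic annotation (one column per assay/cell-type experiment).
* ``F`` (undirected, mean-modifying): 0-1 indicators, by default distance
  windows around the gene's TSS plus an all-ones intercept column.  ``F @ nu``
  is the distance modifier that weights the directed component per SNP.
* ``C`` (undirected, precision-modifying): 0-1 indicators that modify the
  ARD precision of SNP effects.

Directed annotations from sequence-based predictors are dense in raw form but
dominated by near-zero values; they are sparsified by soft-thresholding, strand
averaged, and rescaled so every column has the same 2-norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Soft-threshold applied to raw directed-annotation effects.
DEFAULT_SHRINK_THRESHOLD = 0.008

#: Default TSS distance windows (bp), largest first; each is split into an
#: upstream and a downstream indicator column.
DEFAULT_WINDOW_SIZES = (50_000, 20_000, 10_000, 5_000, 2_000, 1_000, 500, 250)


@dataclass
class DirectedAnnotationMatrix:
    """Signed per-SNP annotation effects ``V`` for one gene (m_j x s)."""

    values: np.ndarray | sp.spmatrix
    snp_ids: list[str]
    annotation_ids: list[str]

    def __post_init__(self) -> None:
        dense = np.asarray(
            self.values.toarray() if sp.issparse(self.values) else self.values,
            dtype=float,
        )
        if not np.all(np.isfinite(dense)):
            bad = np.argwhere(~np.isfinite(dense))
            raise ValueError(f"non-finite directed annotation values at {bad[:5].tolist()}")
        if dense.shape[0] != len(self.snp_ids):
            raise ValueError("row count does not match SNP id count")
        if dense.shape[1] != len(self.annotation_ids):
            raise ValueError("column count does not match annotation id count")
        if len(set(self.annotation_ids)) != len(self.annotation_ids):
            raise ValueError("annotation ids are not unique")

    def toarray(self) -> np.ndarray:
        return np.asarray(
            self.values.toarray() if sp.issparse(self.values) else self.values, dtype=float
        )


@dataclass
class UndirectedAnnotationMatrix:
    """0-1 mean-modifier matrix ``F`` with an all-ones intercept column."""

    values: np.ndarray
    column_labels: list[str]
    intercept_column: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("undirected annotation entries must be 0 or 1")
        if not np.all(v[:, self.intercept_column] == 1.0):
            raise ValueError("intercept column must be all ones")
        self.values = v


@dataclass
class PrecisionAnnotationMatrix:
    """0-1 precision-modifier matrix ``C``."""

    values: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("precision annotation entries must be 0 or 1")
        self.values = v


@dataclass
class MetaAnnotationPartition:
    """Grouping vectors d^l assigning each directed annotation to one group per
    meta-annotation (e.g. one partition by cell type, one by assay type).

    Group indices are 1-based, ``d[l]`` takes values in ``1..h_l``.
    """

    d: list[np.ndarray]
    group_labels: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = [np.asarray(dl, dtype=int) for dl in self.d]
        if not self.group_labels:
            self.group_labels = [
                [f"group{k}" for k in range(1, int(dl.max(initial=0)) + 1)] for dl in self.d
            ]

    @property
    def w(self) -> int:
        return len(self.d)

    @property
    def h(self) -> list[int]:
        return [len(labels) for labels in self.group_labels]


def shrink_directed(values: np.ndarray, threshold: float = DEFAULT_SHRINK_THRESHOLD) -> np.ndarray:
    """Soft-threshold raw directed effects.

    Entries with ``|x| <= threshold`` become 0; the rest are shrunk toward zero
    by ``threshold`` (``x - threshold * sgn(x)``).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(np.atleast_2d(x)))
        raise ValueError(f"non-finite input at coordinates {bad[:5].tolist()}")
    return np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)


def average_strands_and_reshrink(
    fwd: np.ndarray, rev: np.ndarray, threshold: float = DEFAULT_SHRINK_THRESHOLD
) -> np.ndarray:
    """Average the two strand predictions elementwise and re-apply shrinkage."""
    fwd = np.asarray(fwd, dtype=float)
    rev = np.asarray(rev, dtype=float)
    if fwd.shape != rev.shape:
        raise ValueError(f"shape mismatch: {fwd.shape} vs {rev.shape}")
    return shrink_directed((fwd + rev) / 2.0, threshold)


def scale_columns_to_common_norm(
    values: np.ndarray, column_ids: list[str] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Rescale columns so all share the same 2-norm (the mean of input norms).

    Zero-norm columns cannot be rescaled; they are dropped with a warning.
    Returns the rescaled matrix and the indices of the kept columns.
    """
    x = np.asarray(values, dtype=float)
    norms = np.linalg.norm(x, axis=0)
    keep = np.flatnonzero(norms > 0)
    if keep.size == 0:
        raise ValueError("all columns have zero norm")
    if keep.size < x.shape[1]:
        dropped = sorted(set(range(x.shape[1])) - set(keep.tolist()))
        labels = [column_ids[i] for i in dropped] if column_ids else dropped
        logger.warning("dropping %d zero-norm directed annotation columns: %s", len(dropped), labels)
    target = norms[keep].mean()
    scaled = x[:, keep] * (target / norms[keep])
    return scaled, keep.tolist()


def build_distance_windows(
    snp_positions: np.ndarray,
    tss: int,
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
    strand: str = "+",
    cis_window: int | None = None,
) -> UndirectedAnnotationMatrix:
    """Build the 0-1 TSS distance-window matrix ``F``.

    Columns: intercept, then one upstream and one downstream indicator per
    window size. A SNP at signed distance ``delta`` from the TSS is 1 in every
    window with size >= ``|delta|`` on the matching side, so columns on one
    side are nested. A SNP exactly at the TSS counts as downstream (documented
    tie-break). Up/downstream is plus-strand by default; pass ``strand='-'``
    for a gene-strand-aware orientation.
    """
    sizes = tuple(int(s) for s in window_sizes)
    if list(sizes) != sorted(sizes, reverse=True) or len(set(sizes)) != len(sizes):
        raise ValueError("window_sizes must be strictly decreasing")
    pos = np.asarray(snp_positions, dtype=np.int64)
    delta = pos - int(tss)
    if strand == "-":
        delta = -delta
    elif strand != "+":
        raise ValueError(f"unknown strand {strand!r}")
    if cis_window is not None and np.any(np.abs(delta) > cis_window):
        raise ValueError("SNP outside the cis window")
    m = pos.shape[0]
    cols = [np.ones(m)]
    labels = ["intercept"]
    downstream = delta >= 0  # delta == 0 assigned downstream
    for size in sizes:
        inside = np.abs(delta) <= size
        cols.append((inside & ~downstream).astype(float))
        labels.append(f"up_{size}bp")
        cols.append((inside & downstream).astype(float))
        labels.append(f"down_{size}bp")
    return UndirectedAnnotationMatrix(np.column_stack(cols), labels, intercept_column=0)


def validate_partition(
    partition: MetaAnnotationPartition, annotation_ids: list[str]
) -> list[pd.Series]:
    """Check each grouping vector covers every annotation and every group.

    Returns one per-group count table per meta-annotation.
    """
    s = len(annotation_ids)
    tables = []
    for l, dl in enumerate(partition.d):
        if dl.shape[0] != s:
            raise ValueError(
                f"meta-annotation {l}: grouping vector length {dl.shape[0]} != {s} annotations"
            )
        h_l = partition.h[l]
        if dl.min() < 1 or dl.max() > h_l:
            raise ValueError(f"meta-annotation {l}: group indices outside 1..{h_l}")
        counts = np.bincount(dl, minlength=h_l + 1)[1:]
        if np.any(counts == 0):
            empty = [partition.group_labels[l][k] for k in np.flatnonzero(counts == 0)]
            raise ValueError(f"meta-annotation {l}: empty groups {empty}")
        tables.append(pd.Series(counts, index=partition.group_labels[l], name=f"meta_{l}"))
    return tables


def read_partition_table(path: str, annotation_ids: list[str]) -> MetaAnnotationPartition:
    """Read a TSV (annotation_id, meta_annotation_name, group_label) into a partition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    d, group_labels = [], []
    for _, sub in df.groupby("meta_annotation_name", sort=True):
        mapping = dict(zip(sub["annotation_id"], sub["group_label"]))
        missing = [a for a in annotation_ids if a not in mapping]
        if missing:
            raise ValueError(f"annotations missing from partition table: {missing[:5]}")
        labels = sorted(set(mapping.values()))
        index = {g: k + 1 for k, g in enumerate(labels)}
        d.append(np.array([index[mapping[a]] for a in annotation_ids], dtype=int))
        group_labels.append(labels)
    return MetaAnnotationPartition(d=d, group_labels=group_labels)
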