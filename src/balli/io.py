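"""Count-matrix and design-table I/O.

Counts are genes x samples non-negative integers in delimited text with a
header row of sample identifiers and a first column of gene identifiers.
Design tables hold one row per sample; columns are covariates that are split
into nuisance (``Z``, always carrying an intercept) and tested (``X``)
design matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "DesignPair",
    "read_counts",
    "write_counts",
    "filter_low_counts",
    "build_design",
]


@dataclass
class CountMatrix:
    """Genes x samples read counts plus per-sample library sizes.

    ``lib_sizes`` is the column sum of counts at construction time.  When a
    matrix is derived by gene filtering the original library sizes are
    carried along unchanged: the library size of a sample is the total
    sequencing depth over *all* genes, and normalization must see that
    total, not the post-filter one.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lib_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class DesignPair:
    """Nuisance design ``Z`` (first column an intercept) and tested design ``X``.

    For a categorical tested covariate with ``M`` levels, ``X`` has ``M - 1``
    0/1 dummy columns (the last level is the reference), so the test has
    ``M - 1`` degrees of freedom.
    """

    Z: np.ndarray
    X: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.Z.shape[0] != self.X.shape[0]:
            raise ValueError("Z and X must have the same number of rows")
        W = np.hstack([self.Z, self.X])
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("stacked design (Z, X) is rank deficient")

    @property
    def df(self) -> int:
        """Degrees of freedom of the test (number of tested columns)."""
        return self.X.shape[1]


def read_counts(path: str | Path, delimiter: str | None = None) -> CountMatrix:
    """Read a delimited genes x samples count table.

    The delimiter is auto-detected (tab, then comma) unless given
    explicitly.  Cells must parse as non-negative integers; the offending
    gene and sample are named otherwise.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0:
        raise ValueError("no genes in count table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac_ok = np.isfinite(values) & (np.rint(values) == values) & (values >= 0)
        if not frac_ok.all():
            g, s = np.argwhere(~frac_ok)[0]
            raise ValueError(
                f"count for gene {df.index[g]!r}, sample {df.columns[s]!r} "
                f"is not a non-negative integer: {values[g, s]!r}"
            )
        values = values.astype(np.int64)
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_counts(cm: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a count matrix in the layout that :func:`read_counts` accepts."""
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.to_csv(path, sep=delimiter)


def filter_low_counts(cm: CountMatrix) -> CountMatrix:
    """Drop genes whose total count is smaller than one-tenth of the sample size.

    The boundary is kept: a gene with total exactly ``N / 10`` survives.
    Library sizes are *not* recomputed — they remain the column totals over
    all genes, which is what the log-cpm normalization uses.
    """
    threshold = cm.n_samples / 10.0
    keep = cm.counts.sum(axis=1) >= threshold
    if not keep.any():
        raise ValueError("no genes pass filter")
    return CountMatrix(
        [g for g, k in zip(cm.gene_ids, keep) if k],
        list(cm.sample_ids),
        cm.counts[keep],
        lib_sizes=cm.lib_sizes.copy(),
    )


def _dummy_code(values: pd.Series) -> tuple[np.ndarray, list[str], int]:
    levels = list(pd.unique(values))
    M = len(levels)
    cols = np.zeros((len(values), M - 1))
    names = []
    for j, lev in enumerate(levels[:-1]):  # last level is the reference
        cols[:, j] = (values == lev).to_numpy(dtype=float)
        names.append(f"{values.name}[{lev}]")
    return cols, names, M


def build_design(
    sample_table: pd.DataFrame,
    tested: list[str],
    nuisance: list[str] | None = None,
    sample_ids: list[str] | None = None,
    categorical: set[str] | None = None,
) -> DesignPair:
    """Build the (Z, X) design pair from a per-sample covariate table.

    Categorical covariates (object/category dtype, or listed in
    ``categorical``) are dummy-coded with the last observed level as the
    reference; numeric covariates pass through as single columns.  ``Z``
    always starts with an intercept.  If ``sample_ids`` is given the table
    rows are aligned to that order first.
    """
    nuisance = nuisance or []
    categorical = categorical or set()
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in set(sample_table.index.astype(str))]
        if missing:
            raise ValueError(f"samples missing from design table: {missing}")
        sample_table = sample_table.loc[[str(s) for s in sample_ids]]
    N = len(sample_table)

    def encode(names: list[str]) -> tuple[np.ndarray, list[str]]:
        blocks, labels = [], []
        for name in names:
            col = sample_table[name]
            if name in categorical or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype
            ):
                block, names_j, _ = _dummy_code(col)
                if block.shape[1] == 0:
                    raise ValueError(f"covariate {name!r} is constant across samples")
            else:
                block = col.to_numpy(dtype=float).reshape(-1, 1)
                names_j = [name]
            blocks.append(block)
            labels.extend(names_j)
        if blocks:
            return np.hstack(blocks), labels
        return np.empty((N, 0)), labels

    X, x_names = encode(tested)
    Znui, z_names = encode(nuisance)
    Z = np.hstack([np.ones((N, 1)), Znui])
    if X.shape[1] == 0:
        raise ValueError("tested design has no columns")
    W = np.hstack([Z, X])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        names = ["intercept"] + z_names + x_names
        raise ValueError(f"design (Z, X) is rank deficient; columns: {names}")
    return DesignPair(Z=Z, X=X, M=X.shape[1] + 1)
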