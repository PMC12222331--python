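"""Reading, validation, gene prefiltering and normalization of expression matrices.

The substrate of the pipeline is a genes x samples matrix of non-negative
expression values (raw counts or already-normalized).  Two library-size
normalizations are provided: counts-per-million (CPM) and DESeq-style
median-of-ratios size factors.  Prefiltering of sparsely expressed genes is
a separate, optional step because the right sparsity cut-off is
dataset-dependent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

NORMALIZED_FLAGS = ("raw", "cpm", "median_ratio", "external")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix with identifiers and provenance.

    Parameters
    ----------
    values
        Non-negative float array of shape ``(n_genes, n_samples)``.
    gene_ids, sample_ids
        Unique, ordered identifiers for rows and columns.  Gene identifiers
        are treated as opaque strings; no symbol mapping is attempted.
    normalized_flag
        One of ``raw``, ``cpm``, ``median_ratio`` or ``external`` (already
        normalized upstream of this package).
    log_transformed
        Whether ``log2(x + 1)`` was applied (recorded for provenance).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    normalized_flag: str = "raw"
    log_transformed: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if self.normalized_flag not in NORMALIZED_FLAGS:
            raise ValueError(
                f"normalized_flag must be one of {NORMALIZED_FLAGS}, "
                f"got {self.normalized_flag!r}"
            )
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.normalized_flag == "raw" and values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value in raw matrix at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return the matrix as a DataFrame (genes as index, samples as columns)."""
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        normalized_flag: str = "raw",
        log_transformed: bool = False,
    ) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            normalized_flag=normalized_flag,
            log_transformed=log_transformed,
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    normalized_flag: str = "raw",
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    The first column holds gene identifiers, the header row sample
    identifiers.  Gzipped files are accepted (by extension).  Duplicate gene
    or sample identifiers, and non-numeric cells, are rejected with an error
    naming the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    # locate non-numeric cells before coercion so the error can name them
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        original_na = frame[col].isna()
        bad = coerced.isna() & ~original_na
        if bad.any():
            gene = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value at gene {gene!r}, sample {col!r} in {path}"
            )
        if original_na.any():
            gene = frame.index[original_na.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"missing value at gene {gene!r}, sample {col!r} in {path}"
            )
        frame[col] = coerced
    return ExpressionMatrix.from_frame(frame, normalized_flag=normalized_flag)


def write_expression_matrix(
    X: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the matrix in the same dialect ``read_expression_matrix`` accepts."""
    X.to_frame().to_csv(path, sep=delimiter)


def filter_sparse_genes(
    X: ExpressionMatrix, min_nonzero_fraction: float = 0.25
) -> ExpressionMatrix:
    """Remove genes expressed in fewer than a fraction of samples.

    A gene is kept iff its number of samples with value > 0 is at least
    ``min_nonzero_fraction * n_samples`` — the comparison is ``>=`` with no
    rounding of the product, so "at least one fourth" of 8 samples means 2
    non-zero samples suffice.  Gene order and the sample set are unchanged;
    the operation is idempotent.
    """
    if not 0 < min_nonzero_fraction <= 1:
        raise ValueError("min_nonzero_fraction must be in (0, 1]")
    nonzero = (X.values > 0).sum(axis=1)
    keep = nonzero >= min_nonzero_fraction * X.n_samples
    if not keep.any():
        raise ValueError(
            "all genes removed by sparsity filter; relax min_nonzero_fraction "
            f"(currently {min_nonzero_fraction})"
        )
    return replace(
        X,
        values=X.values[keep],
        gene_ids=tuple(g for g, k in zip(X.gene_ids, keep) if k),
    )


def cpm_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: scale every sample column to sum to 1e6."""
    colsums = X.values.sum(axis=0)
    zero = colsums <= 0
    if zero.any():
        raise ValueError(
            f"sample {X.sample_ids[int(np.argmax(zero))]!r} has zero total counts"
        )
    return replace(X, values=X.values / colsums * 1e6, normalized_flag="cpm")


def median_ratio_size_factors(values: np.ndarray) -> np.ndarray:
    """DESeq-style size factors for a raw count matrix (genes x samples).

    The reference is the per-gene geometric mean across samples, restricted to
    genes with non-zero counts in every sample; each sample's size factor is
    the median over those genes of count / reference.
    """
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has non-zero counts in every sample; median-ratio "
            "normalization needs at least one (consider adding a pseudo-count "
            "or using CPM)"
        )
    ref = np.exp(np.mean(np.log(values[all_nonzero]), axis=1))
    return np.median(values[all_nonzero] / ref[:, None], axis=0)


def median_ratio_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios library-size normalization (DESeq size factors)."""
    factors = median_ratio_size_factors(X.values)
    return replace(X, values=X.values / factors, normalized_flag="median_ratio")


def log2_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Optional ``log2(x + 1)`` transform, off by default in the pipeline."""
    return replace(X, values=np.log2(X.values + 1.0), log_transformed=True)


def write_run_metadata(path: str | Path, **fields) -> None:
    """Append-style provenance record (normalization, filtering, seeds...)."""
    Path(path).write_text(json.dumps(fields, indent=2, default=str) + "\n")
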