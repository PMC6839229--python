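"""Validation helpers for sample-by-gene matrices.

A matrix is a :class:`pandas.DataFrame` with unique sample IDs as the
index and unique gene IDs as the columns.  A *continuous* matrix holds
real measurements (expression, methylation beta values, ...); a *binary*
matrix holds the {0,1} dysregulation indicators that double as the
transaction database for rule mining (samples are transactions, genes
are items).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class MatrixError(ValueError):
    """Raised when a sample-by-gene matrix violates its contract."""


def _check_unique(labels, kind: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = sorted(seen[seen.duplicated()].unique().tolist())
        raise MatrixError(f"duplicate {kind} IDs: {dupes}")


def validate_matrix(M: pd.DataFrame, *, allow_missing: bool = True) -> pd.DataFrame:
    """Validate a continuous samples-by-genes matrix, returning it unchanged."""
    if not isinstance(M, pd.DataFrame):
        raise MatrixError(f"expected a pandas DataFrame, got {type(M).__name__}")
    if M.shape[0] == 0 or M.shape[1] == 0:
        raise MatrixError("empty matrix: need at least one sample and one gene")
    _check_unique(M.index, "sample")
    _check_unique(M.columns, "gene")
    if not allow_missing and M.isna().to_numpy().any():
        raise MatrixError("matrix contains missing values")
    return M


def validate_binary(B: pd.DataFrame) -> pd.DataFrame:
    """Validate a {0,1} matrix (the transaction database)."""
    validate_matrix(B, allow_missing=False)
    vals = B.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))]
        raise MatrixError(f"binary matrix contains non-0/1 entries, e.g. {bad.flat[0]!r}")
    return B


def check_aligned(M: pd.DataFrame, B: pd.DataFrame) -> None:
    """Require identical sample and gene labels (same order) in M and B."""
    if not M.index.equals(B.index):
        raise MatrixError("continuous and binary matrices have different sample IDs")
    if not M.columns.equals(B.columns):
        raise MatrixError("continuous and binary matrices have different gene IDs")
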