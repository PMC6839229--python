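"""Delimited-text I/O for matrices and rule tables.

Matrix files follow the common sample-by-gene layout: one header row of
gene IDs, one leading column of sample IDs, numeric cells.  Files with
genes in rows are accepted via ``orientation='genes_in_rows'`` and
transposed on read.  Rule tables are TSV with the fixed column order
``lhs, rhs, support, confidence, lift, wcs, lamda3``.
"""

from __future__ import annotations

import csv
import math
import os
import numpy as np
import pandas as pd

from .arm import Rule, RuleMetrics, rules_to_frame
from .matrix import MatrixError, validate_matrix

__all__ = ["read_matrix", "write_matrix", "write_rule_table", "read_rule_table"]

#: cell contents treated as missing (case-insensitive)
MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}

RULE_COLUMNS = ["lhs", "rhs", "support", "confidence", "lift", "wcs", "lamda3"]


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_matrix(
    path,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a labelled numeric matrix into samples-by-genes orientation.

    Parameters
    ----------
    path : str or Path
        Delimited text file; first row and first column are labels.
    orientation : {'samples_in_rows', 'genes_in_rows'}
        On-disk layout; the returned frame always has samples in rows.
    delimiter : str, optional
        Defaults to tab, or comma for ``.csv`` files.

    Missing cells (empty or any of ``NA``, ``NaN``, ``N/A``, ``null``,
    case-insensitive) become ``NaN``.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    sep = _delimiter_for(path, delimiter)

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r]  # ignore fully blank lines
    if len(rows) < 2 or len(rows[0]) < 2:
        raise MatrixError(f"{path}: no data rows/columns found")

    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )

    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels = [r[0].strip() for r in rows[1:]]

    def parse(cell: str, lineno: int) -> float:
        cell = cell.strip()
        if cell.lower() in MISSING_TOKENS:
            return math.nan
        try:
            return float(cell)
        except ValueError:
            raise MatrixError(
                f"{path}: line {lineno}: cannot parse {cell!r} as a number"
            ) from None

    values = [
        [parse(cell, lineno) for cell in row[1:]]
        for lineno, row in enumerate(rows[1:], start=2)
    ]
    M = pd.DataFrame(np.array(values, dtype=float), index=row_labels, columns=col_labels)
    if orientation == "genes_in_rows":
        M = M.T
    return validate_matrix(M)


def write_matrix(M: pd.DataFrame, path, delimiter: str | None = None) -> None:
    """Write a samples-by-genes matrix with labels; NaN written as ``NA``."""
    sep = _delimiter_for(path, delimiter)
    validate_matrix(M)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow([""] + [str(g) for g in M.columns])
        for sid, row in zip(M.index, M.to_numpy()):
            writer.writerow([str(sid)] + [_fmt(v) for v in row])


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    f = float(v)
    return repr(int(f)) if f.is_integer() and abs(f) < 1e15 else repr(f)


def write_rule_table(rules, path) -> None:
    """Write rules as TSV with columns lhs, rhs, support, confidence, lift, wcs, lamda3.

    ``rules`` may be a sequence of :class:`~rulomics.arm.Rule` or an
    equivalent DataFrame.  Items within lhs/rhs are comma-joined in sorted
    order; missing measures are written as ``NA``; numbers use shortest
    round-trip formatting so a re-read reproduces them exactly.
    """
    frame = rules if isinstance(rules, pd.DataFrame) else rules_to_frame(rules)
    if list(frame.columns) != RULE_COLUMNS:
        raise ValueError(f"rule table columns must be {RULE_COLUMNS}")
    for lhs, rhs in zip(frame["lhs"], frame["rhs"]):
        if set(str(lhs).split(",")) & set(str(rhs).split(",")):
            raise ValueError(f"rule has overlapping sides: {lhs} => {rhs}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RULE_COLUMNS)
        for _, row in frame.iterrows():
            writer.writerow(
                [row["lhs"], row["rhs"]] + [_fmt(row[c]) for c in RULE_COLUMNS[2:]]
            )


def read_rule_table(path) -> list[Rule]:
    """Read a rule table written by :func:`write_rule_table`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != RULE_COLUMNS:
            raise ValueError(f"{path}: unexpected rule-table header {header}")
        rules = []
        for row in reader:
            if not row:
                continue
            lhs = tuple(sorted(row[0].split(",")))
            rhs = tuple(sorted(row[1].split(",")))
            nums = [None if c == "NA" else float(c) for c in row[2:7]]
            rules.append(Rule(lhs, rhs, RuleMetrics(*nums)))
    return rules
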