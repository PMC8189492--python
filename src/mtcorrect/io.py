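"""Reading p-value tables and writing result tables as CSV/TSV.

Input tables are one p-value per row, comma- or tab-delimited
(auto-detected, overridable), with an optional header and an optional
identifier column.  Output tables round-trip through :func:`read_results`
without loss at better than 12 significant digits (floats are written
with ``repr`` precision).
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AdjustmentResult, PValueCollection, validate_pvalues
from .fdr import QValueResult

__all__ = ["read_pvalue_table", "write_results", "read_results"]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_pvalue_table(
    path: str | Path,
    column: str | None = None,
    delimiter: str | None = None,
) -> PValueCollection:
    """Read a CSV/TSV table of p-values into a validated collection.

    Accepts a headerless single column, a headered single column, or a
    two-column (id, p) layout; with more columns, ``column`` selects the
    p-value column by header name.  Blank lines are skipped and row order
    is preserved.  Unparseable cells raise with the 1-based data row
    number; ids are generated (``row1`` ...) when no id column exists.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])

    rows = [
        row
        for row in csv.reader(_io.StringIO(text), delimiter=delimiter)
        if any(cell.strip() for cell in row)
    ]

    def _is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    header: list[str] | None = None
    first = rows[0]
    if not all(_is_number(c) for c in first if c.strip()):
        header = [c.strip() for c in first]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: no data rows below the header")

    ncol = max(len(r) for r in rows)
    if column is not None:
        if header is None or column not in header:
            raise ValueError(f"{path}: no column named {column!r}")
        p_idx = header.index(column)
        id_idx = 0 if p_idx != 0 and ncol > 1 else None
    elif ncol == 1:
        p_idx, id_idx = 0, None
    elif ncol == 2:
        # id column is the one whose first data cell is not numeric;
        # with two numeric columns, treat the first as the id.
        p_idx, id_idx = (1, 0) if _is_number(rows[0][1].strip()) else (0, 1)
        if id_idx == 1 and not _is_number(rows[0][0].strip()):
            raise ValueError(f"{path}: no numeric p-value column found in row 1")
    else:
        raise ValueError(
            f"{path}: {ncol} columns found; pass column= to name the p-value column"
        )

    pvals: list[float] = []
    ids: list[str] = []
    for i, row in enumerate(rows, start=1):
        if len(row) <= p_idx or not row[p_idx].strip():
            raise ValueError(f"{path}: missing p-value in data row {i}")
        cell = row[p_idx].strip()
        try:
            pvals.append(float(cell))
        except ValueError:
            raise ValueError(
                f"{path}: unparseable p-value {cell!r} in data row {i}"
            ) from None
        ids.append(row[id_idx].strip() if id_idx is not None else f"row{i}")
    try:
        return validate_pvalues(pvals, ids=ids)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def _ids_for(result, n: int) -> list[str]:
    return list(result.ids) if result.ids else [f"row{i+1}" for i in range(n)]


def write_results(result, path: str | Path) -> None:
    """Write an adjustment result, q-value result or performance table as CSV.

    Adjustment results get columns ``id, p_raw, adjusted, rejected,
    method, parameters``; q-value results use a ``q_value`` column and
    record pi0 and its estimator in ``#``-prefixed comment header lines.
    A performance DataFrame is written as-is.
    """
    path = Path(path)
    if isinstance(result, AdjustmentResult):
        params = ";".join(f"{k}={v}" for k, v in result.params.items())
        df = pd.DataFrame(
            {
                "id": _ids_for(result, len(result.pvalues)),
                "p_raw": [repr(float(x)) for x in result.pvalues],
                "adjusted": [repr(float(x)) for x in result.adjusted],
                "rejected": [bool(x) for x in result.rejected],
                "method": result.method,
                "parameters": f"alpha={result.alpha!r}" + (f";{params}" if params else ""),
            }
        )
        df.to_csv(path, index=False)
    elif isinstance(result, QValueResult):
        header = (
            f"# method=qvalue pi0={result.pi0.value!r} "
            f"pi0_estimator={result.pi0.estimator} n={result.pi0.n_used}\n"
        )
        df = pd.DataFrame(
            {
                "id": _ids_for(result, len(result.pvalues)),
                "p_raw": [repr(float(x)) for x in result.pvalues],
                "q_value": [repr(float(x)) for x in result.qvalues],
            }
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results` (skips comments)."""
    return pd.read_csv(path, comment="#")
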