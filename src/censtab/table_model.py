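"""Censored two-way tables of a continuous outcome.

A *censored table* here is a contingency-style layout of a continuous
measurement (e.g. antioxidant content in percent) indexed by an ordinal
integer row variable (vintage year) and a categorical column variable
(wine source), in which some cells were never measured.  The missing
cells are the object of the iterative estimation algorithm in
:mod:`censtab.imputer`; this module only represents, validates and
round-trips the tables and their margins.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CensoredTable",
    "MarginSet",
    "TableValidationError",
    "load_table",
    "save_table",
    "margins",
    "subtable",
]

#: strings accepted as a missing cell on read (besides the empty field)
NA_TOKENS = ("", "NA", "NaN", "nan")

#: relative tolerance for the margin consistency identity
MARGIN_RTOL = 1e-9


class TableValidationError(ValueError):
    """Raised when a table breaks a structural invariant."""


@dataclass(frozen=True)
class CensoredTable:
    """A two-way table of a continuous outcome with a missing-cell mask.

    Parameters
    ----------
    row_labels
        Strictly increasing integer row labels (calendar years).
    col_labels
        Unique string column labels (source identifiers).
    values
        ``(n_rows, n_cols)`` float matrix; entries at masked-out cells are
        stored as NaN and carry no information.
    observed_mask
        Boolean matrix, ``True`` where the cell was experimentally
        observed.  Observed cells are immutable through every downstream
        operation: the algorithms only ever write into masked cells.
    """

    row_labels: tuple[int, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_labels", tuple(int(r) for r in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(c) for c in self.col_labels))
        vals = np.asarray(self.values, dtype=float).copy()
        mask = np.asarray(self.observed_mask, dtype=bool).copy()
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise TableValidationError(
                f"values shape {vals.shape} does not match labels "
                f"({len(self.row_labels)} rows x {len(self.col_labels)} cols)"
            )
        if mask.shape != vals.shape:
            raise TableValidationError("observed_mask shape does not match values")
        if any(b <= a for a, b in zip(self.row_labels, self.row_labels[1:])):
            raise TableValidationError("row labels must be strictly increasing integers")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise TableValidationError("column labels must be unique")
        if not np.all(np.isfinite(vals[mask])):
            raise TableValidationError("observed cells must hold finite values")
        vals[~mask] = np.nan
        # a column with missing cells needs a fitted line, hence >= 2 points
        n_obs = mask.sum(axis=0)
        n_miss = (~mask).sum(axis=0)
        short = [
            c for c, n, m in zip(self.col_labels, n_obs, n_miss) if m > 0 and n < 2
        ]
        if short:
            raise TableValidationError(
                f"columns {short} have missing cells but fewer than 2 observed "
                "cells; a line cannot be fitted through fewer than two points"
            )
        vals.flags.writeable = False
        mask.flags.writeable = False
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "observed_mask", mask)

    # -- basic geometry ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    @property
    def n_missing(self) -> int:
        return int((~self.observed_mask).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    @property
    def years(self) -> np.ndarray:
        """Row labels as a float vector (for regression design)."""
        return np.asarray(self.row_labels, dtype=float)

    def ages(self, analysis_year: int = 2010) -> np.ndarray:
        """Row labels converted to ages at the analysis date.

        The outcome was measured for every sample at a single analysis
        date, so age is an affine view of the vintage year:
        ``analysis_year - year``.
        """
        return float(analysis_year) - self.years

    # -- derived tables ------------------------------------------------

    def with_filled(self, filled_values: np.ndarray) -> "CensoredTable":
        """Return a complete copy whose missing cells come from *filled_values*.

        Observed cells are taken from ``self`` regardless of what
        *filled_values* holds there, enforcing observed-cell immutability.
        """
        filled_values = np.asarray(filled_values, dtype=float)
        if filled_values.shape != self.shape:
            raise TableValidationError("filled_values shape mismatch")
        out = np.where(self.observed_mask, self.values, filled_values)
        if not np.all(np.isfinite(out)):
            raise TableValidationError("filled table contains non-finite cells")
        return CensoredTable(
            self.row_labels, self.col_labels, out, np.ones(self.shape, dtype=bool)
        )

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by year, NaN at missing cells."""
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        ).rename_axis("year")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CensoredTable):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.observed_mask, other.observed_mask)
            and np.array_equal(
                np.nan_to_num(self.values), np.nan_to_num(other.values)
            )
        )


@dataclass(frozen=True)
class MarginSet:
    """Row sums, column sums and grand total of a complete table."""

    row_sums: np.ndarray
    col_sums: np.ndarray
    grand_total: float

    def __post_init__(self) -> None:
        rs = np.asarray(self.row_sums, dtype=float)
        cs = np.asarray(self.col_sums, dtype=float)
        g = float(self.grand_total)
        scale = max(abs(g), 1.0)
        if abs(rs.sum() - g) > MARGIN_RTOL * scale or abs(cs.sum() - g) > MARGIN_RTOL * scale:
            raise TableValidationError(
                "margin inconsistency: row sums and column sums must both "
                "add up to the grand total"
            )
        object.__setattr__(self, "row_sums", rs)
        object.__setattr__(self, "col_sums", cs)
        object.__setattr__(self, "grand_total", g)


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def load_table(path: str | Path | io.IOBase, **csv_options) -> CensoredTable:
    """Read a censored table from CSV.

    Layout: a header row of column labels, a first column of integer
    years, one row per year.  An empty field or a literal ``NA`` marks a
    missing cell.  Any extra keyword arguments are passed to
    :func:`pandas.read_csv`.
    """
    df = pd.read_csv(
        path, index_col=0, na_values=list(NA_TOKENS), keep_default_na=False,
        **csv_options,
    )
    try:
        years = [int(y) for y in df.index]
    except (TypeError, ValueError) as exc:
        raise TableValidationError(f"non-integer year label in first column: {exc}") from exc
    if len(set(years)) != len(years):
        raise TableValidationError("duplicate year in first column")
    vals = df.to_numpy(dtype=float)  # raises on non-numeric data cells
    mask = ~np.isnan(vals)
    return CensoredTable(tuple(years), tuple(df.columns), vals, mask)


def save_table(table: CensoredTable, path: str | Path | io.IOBase) -> None:
    """Write a censored table back to CSV (missing cells as empty fields)."""
    table.to_frame().to_csv(path, na_rep="")


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def margins(filled: CensoredTable) -> MarginSet:
    """Row/column sums and grand total of a fully observed table.

    Margins are undefined while any cell is missing; call
    :func:`censtab.imputer.iterate` first to fill the table.
    """
    if not filled.is_complete:
        raise TableValidationError(
            f"margins are undefined for a censored table "
            f"({filled.n_missing} cells missing)"
        )
    v = filled.values
    return MarginSet(v.sum(axis=1), v.sum(axis=0), float(v.sum()))


def subtable(
    t: CensoredTable, rows: Sequence[int], cols: Sequence[str]
) -> CensoredTable:
    """Extract the sub-table at the given year and source labels.

    Values, mask and the *requested* label order are preserved.
    """
    try:
        ri = [t.row_labels.index(int(r)) for r in rows]
    except ValueError as exc:
        raise KeyError(f"unknown year label: {exc}") from exc
    try:
        ci = [t.col_labels.index(str(c)) for c in cols]
    except ValueError as exc:
        raise KeyError(f"unknown source label: {exc}") from exc
    return CensoredTable(
        tuple(t.row_labels[i] for i in ri),
        tuple(t.col_labels[j] for j in ci),
        t.values[np.ix_(ri, ci)],
        t.observed_mask[np.ix_(ri, ci)],
    )
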