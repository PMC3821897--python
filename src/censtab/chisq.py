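"""Expected tables under independence and the X² discrepancy statistic.

The expected value of a cell under row x column independence is
``row_sum * col_sum / grand_total``, and the discrepancy between a table
and its expectation is ``X² = Σ (O - E)² / E``.  Here both are applied
to *continuous* percentage values, not counts: X² serves as the
objective the iterative filling algorithm tracks, and its chi-square
tail probability is reported for information only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .linreg import tail_probabilities
from .table_model import CensoredTable, TableValidationError, margins

__all__ = ["ChiSquareResult", "expected_table", "chi_square"]


@dataclass(frozen=True)
class ChiSquareResult:
    """Expected table, X² statistic, degrees of freedom and p-value."""

    expected: np.ndarray
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "expected": np.asarray(self.expected).tolist(),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def expected_table(filled: CensoredTable | np.ndarray) -> np.ndarray:
    """Cell-wise expectations ``E[i,j] = row_sum[i] * col_sum[j] / total``.

    Accepts a complete :class:`~censtab.table_model.CensoredTable` or a
    bare matrix.  All cells must be present and positive: expectations
    built from nonpositive margins are meaningless for X².
    """
    if isinstance(filled, CensoredTable):
        m = margins(filled)  # raises if any cell is missing
        values = filled.values
        row_sums, col_sums, total = m.row_sums, m.col_sums, m.grand_total
    else:
        values = np.asarray(filled, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if np.isnan(values).any():
            raise TableValidationError("expected_table needs a complete table")
        row_sums = values.sum(axis=1)
        col_sums = values.sum(axis=0)
        total = float(values.sum())
    if np.any(values <= 0):
        raise ValueError("all cells must be positive for a meaningful X²")
    if total <= 0:
        raise ValueError("grand total must be positive")
    return np.outer(row_sums, col_sums) / total


def chi_square(observed: np.ndarray, expected: np.ndarray) -> ChiSquareResult:
    """``X² = Σ (O − E)² / E`` with ``df = (rows−1)(cols−1)``.

    *observed* and *expected* must have the same shape and every
    expected cell must be positive.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape} vs expected {expected.shape}"
        )
    if observed.ndim != 2:
        raise ValueError("chi_square expects 2-D matrices")
    if np.any(expected <= 0):
        raise ValueError("every expected cell must be positive")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    n_rows, n_cols = observed.shape
    df = max((n_rows - 1) * (n_cols - 1), 1)
    return ChiSquareResult(
        expected=expected,
        statistic=statistic,
        df=df,
        p_value=tail_probabilities(statistic, "chi2", df),
    )
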