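"""Iterative estimation of the missing cells of a censored table.

The algorithm alternates two complementary fills of the missing cells
and tracks the X² discrepancy between the current filled table and its
independence expectation:

0. *initial fill*: per column, fit a least-squares line of the outcome
   against the year on that column's observed cells only, and write the
   line value into each missing cell;
1. compute the expected table from the margins of the current filled
   table;
2. compute X² between the filled table and the expected table;
3. overwrite the (originally) missing cells with their expected values;
4. refit each column's line;
5. overwrite the missing cells with the refitted line values;
6. stop once two consecutive X² values differ by less than the
   tolerance, otherwise return to step 1.

Observed cells are never written: steps 3 and 5 only touch cells that
were missing in the input.  The X² sequence is not guaranteed to be
monotone — on the benchmark wine table it passes a local minimum and
then creeps up slightly before the stopping rule fires — so the index
of the smallest X² is recorded separately from the stopping index.

Algorithmic variants
--------------------
The step list above leaves a few choices open; they are all exposed on
:class:`ImputerConfig` and enumerable with :func:`search_variants`:

* which cells enter X² (the experimentally observed cells only, or all
  cells of the filled table);
* which data feed the per-column refit in step 4 (the full filled
  column, or the observed cells only — the latter makes the iteration
  stationary after the first cycle);
* the working precision (values written into the table and expected
  values used in X² rounded to a fixed number of decimals, emulating an
  analysis carried out at the printed precision of the table, or full
  floating-point precision);
* whether the stopping test runs at the end of the cycle, after the
  fills (the step order above), or immediately after X².

The shipped default — observed-cell X², refit on the filled columns,
two-decimal working precision, end-of-cycle stop — is the configuration
:func:`search_variants` locks in on the benchmark wine table: it
reproduces the published filled and expected matrices to within one
unit of the last printed digit and stops after 59 iterations with the
local minimum at iteration 7.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .chisq import expected_table
from .table_model import CensoredTable

__all__ = [
    "ImputerConfig",
    "IterationRecord",
    "ImputationResult",
    "VariantReport",
    "initial_fill",
    "iterate",
    "trace_to_series",
    "search_variants",
    "DEFAULT_CONFIG",
]

#: slope/intercept pairs keyed by column label (columns with missing cells)
ColumnLineCoefficients = dict[str, tuple[float, float]]


@dataclass(frozen=True)
class ImputerConfig:
    """Tunable choices of the iterative algorithm.

    Parameters
    ----------
    tolerance
        Stop once ``|X²_k − X²_{k−1}|`` falls below this (must be > 0).
    max_iterations
        Hard cap on cycles; hitting it is reported via ``stop_reason``,
        not raised.
    chi_cells
        ``"observed"``: X² runs over the experimentally observed cells
        only.  ``"all"``: over every cell of the filled table.
    refit_data
        ``"filled"``: step-4 refits use the full column as currently
        filled.  ``"observed"``: refits use the observed cells only.
    round_to
        Working precision in decimals: every value written into the
        table and every expected value entering X² is rounded to this
        many decimals.  ``None`` keeps full float precision.
    stop_check
        ``"end_of_cycle"``: the stopping test runs after the fills of
        the current cycle.  ``"after_chi"``: it runs immediately after
        X², so the stopping cycle performs no fills.
    """

    tolerance: float = 1e-4
    max_iterations: int = 10_000
    chi_cells: Literal["observed", "all"] = "observed"
    refit_data: Literal["filled", "observed"] = "filled"
    round_to: int | None = 2
    stop_check: Literal["end_of_cycle", "after_chi"] = "end_of_cycle"

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.chi_cells not in ("observed", "all"):
            raise ValueError(f"unknown chi_cells: {self.chi_cells!r}")
        if self.refit_data not in ("filled", "observed"):
            raise ValueError(f"unknown refit_data: {self.refit_data!r}")
        if self.stop_check not in ("end_of_cycle", "after_chi"):
            raise ValueError(f"unknown stop_check: {self.stop_check!r}")

    def _round(self, a: np.ndarray) -> np.ndarray:
        if self.round_to is None:
            return a
        return np.round(a, self.round_to)

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "max_iterations": self.max_iterations,
            "chi_cells": self.chi_cells,
            "refit_data": self.refit_data,
            "round_to": self.round_to,
            "stop_check": self.stop_check,
        }


#: configuration locked by the variant search on the benchmark wine table
DEFAULT_CONFIG = ImputerConfig()


@dataclass(frozen=True)
class IterationRecord:
    """State of one cycle: X² and the table it was computed on.

    ``filled_values`` is the full table at the moment X² was evaluated;
    ``coefficients`` are the per-column lines refitted later in the same
    cycle (``None`` when the cycle stopped before refitting).
    """

    iteration: int
    chi2: float
    filled_values: np.ndarray
    coefficients: ColumnLineCoefficients | None


@dataclass(frozen=True)
class ImputationResult:
    """Outcome of :func:`iterate`."""

    filled_table: CensoredTable
    expected: np.ndarray
    final_coefficients: ColumnLineCoefficients
    trace: tuple[IterationRecord, ...]
    stop_reason: Literal["tolerance reached", "max iterations"]
    config: ImputerConfig

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def argmin_iteration(self) -> int:
        """1-based index of the smallest X² in the trace."""
        chis = [rec.chi2 for rec in self.trace]
        return int(np.argmin(chis)) + 1

    @property
    def final_chi2(self) -> float:
        return self.trace[-1].chi2

    def to_report(self) -> dict:
        """JSON-serializable summary (coefficients, X², stopping facts)."""
        return {
            "config": self.config.to_dict(),
            "n_iterations": self.n_iterations,
            "argmin_iteration": self.argmin_iteration,
            "final_chi2": self.final_chi2,
            "min_chi2": float(min(rec.chi2 for rec in self.trace)),
            "stop_reason": self.stop_reason,
            "final_coefficients": {
                col: {"slope": s, "intercept": b}
                for col, (s, b) in self.final_coefficients.items()
            },
        }


def _line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least-squares line (matches :func:`fit_ols` exactly)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("cannot fit a line: the x values coincide")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    return slope, float(ym - slope * xm)


def _fit_columns(
    table: CensoredTable,
    values: np.ndarray,
    use_mask: np.ndarray | None,
) -> ColumnLineCoefficients:
    """Per-column lines of value vs year, only for columns with gaps."""
    coeffs: ColumnLineCoefficients = {}
    years = table.years
    for j, col in enumerate(table.col_labels):
        if table.observed_mask[:, j].all():
            continue
        sel = use_mask[:, j] if use_mask is not None else slice(None)
        x = years[sel]
        if np.unique(x).size < 2:
            raise ValueError(
                f"column {col!r}: observed cells share a single year; "
                "a line cannot be fitted"
            )
        coeffs[col] = _line(x, values[sel, j])
    return coeffs


def _apply_lines(
    table: CensoredTable,
    values: np.ndarray,
    coeffs: ColumnLineCoefficients,
    config: ImputerConfig,
) -> None:
    """Write line values into the missing cells of *values*, in place."""
    years = table.years
    for j, col in enumerate(table.col_labels):
        if col not in coeffs:
            continue
        miss = ~table.observed_mask[:, j]
        slope, intercept = coeffs[col]
        values[miss, j] = config._round(slope * years[miss] + intercept)


def initial_fill(
    t: CensoredTable, config: ImputerConfig | None = None
) -> tuple[CensoredTable, ColumnLineCoefficients]:
    """Fill every missing cell from its column's observed-cell line.

    Coefficients are returned only for columns that contain missing
    cells; a complete table comes back unchanged with no coefficients.
    By default fills are exact line values; pass a config with
    ``round_to`` set to work at a fixed printed precision.
    """
    config = config or ImputerConfig(round_to=None)
    values = np.where(t.observed_mask, t.values, np.nan)
    coeffs = _fit_columns(t, values, t.observed_mask)
    _apply_lines(t, values, coeffs, config)
    return t.with_filled(values), coeffs


def iterate(t: CensoredTable, config: ImputerConfig = DEFAULT_CONFIG) -> ImputationResult:
    """Run the full iterative fill/expected/refit algorithm.

    Returns the converged filled table (observed cells untouched), its
    expected table, the final per-column coefficients and the complete
    per-iteration trace.  Non-convergence within ``max_iterations`` is
    reported through ``stop_reason``; a nonpositive expected cell aborts
    with a diagnostic because X² would be undefined.
    """
    obs = t.observed_mask
    chi_mask = obs if config.chi_cells == "observed" else np.ones_like(obs)

    if t.is_complete:
        expected = expected_table(t.values)
        echk = config._round(expected)
        chi2 = float(((t.values[chi_mask] - echk[chi_mask]) ** 2 / echk[chi_mask]).sum())
        rec = IterationRecord(1, chi2, t.values.copy(), {})
        return ImputationResult(
            filled_table=t.with_filled(t.values),
            expected=expected,
            final_coefficients={},
            trace=(rec,),
            stop_reason="tolerance reached",
            config=config,
        )

    filled, coeffs = initial_fill(t, config)
    values = filled.values.copy()

    trace: list[IterationRecord] = []
    prev_chi2: float | None = None
    stop_reason: str = "max iterations"

    for iteration in range(1, config.max_iterations + 1):
        expected = expected_table(values)
        e_chk = config._round(expected)
        if np.any(e_chk <= 0):
            raise RuntimeError(
                f"iteration {iteration}: nonpositive expected cell "
                f"(min {e_chk.min():.4g}); X² is undefined"
            )
        chi2 = float(
            ((values[chi_mask] - e_chk[chi_mask]) ** 2 / e_chk[chi_mask]).sum()
        )
        snapshot = values.copy()

        if (
            config.stop_check == "after_chi"
            and prev_chi2 is not None
            and abs(chi2 - prev_chi2) < config.tolerance
        ):
            trace.append(IterationRecord(iteration, chi2, snapshot, None))
            stop_reason = "tolerance reached"
            break

        # step 3: expected values into the missing cells
        values[~obs] = config._round(expected[~obs])
        # step 4: refit the column lines
        use_mask = None if config.refit_data == "filled" else obs
        coeffs = _fit_columns(t, values, use_mask)
        # step 5: line values into the missing cells
        _apply_lines(t, values, coeffs, config)

        trace.append(IterationRecord(iteration, chi2, snapshot, dict(coeffs)))

        if (
            config.stop_check == "end_of_cycle"
            and prev_chi2 is not None
            and abs(chi2 - prev_chi2) < config.tolerance
        ):
            stop_reason = "tolerance reached"
            break
        prev_chi2 = chi2

    assert np.array_equal(values[obs], t.values[obs]), "observed cells were modified"
    return ImputationResult(
        filled_table=t.with_filled(values),
        expected=expected_table(values),
        final_coefficients=coeffs,
        trace=tuple(trace),
        stop_reason=stop_reason,  # type: ignore[arg-type]
        config=config,
    )


def trace_to_series(r: ImputationResult) -> list[tuple[int, float]]:
    """The X² trajectory as ``(iteration, X²)`` pairs, ready to plot."""
    return [(rec.iteration, rec.chi2) for rec in r.trace]


# ---------------------------------------------------------------------
# variant search
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class VariantReport:
    """Agreement of one algorithm variant with a reference solution."""

    config: ImputerConfig
    max_filled_diff: float
    max_expected_diff: float
    n_iterations: int
    argmin_iteration: int
    stop_reason: str

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "max_filled_diff": self.max_filled_diff,
            "max_expected_diff": self.max_expected_diff,
            "n_iterations": self.n_iterations,
            "argmin_iteration": self.argmin_iteration,
            "stop_reason": self.stop_reason,
        }


def search_variants(
    t: CensoredTable,
    reference_filled: np.ndarray,
    reference_expected: np.ndarray | None = None,
    *,
    tolerance: float = 1e-4,
    max_iterations: int = 10_000,
    round_choices: tuple[int | None, ...] = (2, None),
) -> list[VariantReport]:
    """Run every enumerable algorithm variant and rank by fidelity.

    Variants are ranked by the largest absolute deviation of their
    converged filled table from *reference_filled* (ties broken on the
    expected-table deviation, then on iteration count).  The top-ranked
    configuration is the one to ship as a default for data of this kind.
    """
    reference_filled = np.asarray(reference_filled, dtype=float)
    if reference_expected is not None:
        reference_expected = np.asarray(reference_expected, dtype=float)
    reports = []
    for chi_cells, refit_data, round_to, stop_check in itertools.product(
        ("observed", "all"), ("filled", "observed"), round_choices,
        ("end_of_cycle", "after_chi"),
    ):
        cfg = ImputerConfig(
            tolerance=tolerance,
            max_iterations=max_iterations,
            chi_cells=chi_cells,
            refit_data=refit_data,
            round_to=round_to,
            stop_check=stop_check,
        )
        res = iterate(t, cfg)
        d_fill = float(np.abs(res.filled_table.values - reference_filled).max())
        d_exp = (
            float(np.abs(res.expected - reference_expected).max())
            if reference_expected is not None
            else float("nan")
        )
        reports.append(
            VariantReport(
                config=cfg,
                max_filled_diff=d_fill,
                max_expected_diff=d_exp,
                n_iterations=res.n_iterations,
                argmin_iteration=res.argmin_iteration,
                stop_reason=res.stop_reason,
            )
        )
    reports.sort(
        key=lambda r: (
            r.max_filled_diff,
            r.max_expected_diff if np.isfinite(r.max_expected_diff) else np.inf,
            r.n_iterations,
        )
    )
    return reports
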