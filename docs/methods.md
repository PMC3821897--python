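# Methods

## Data model

A *censored table* is an `n_years × n_sources` matrix of a continuous
outcome (antioxidant content, in percent) with a boolean observed-cell
mask. Rows are strictly increasing calendar years; "censored" follows
the field usage of the benchmark study and simply means a cell that was
never measured — no survival-style censoring semantics are implied.
Two invariants are enforced throughout: observed cells are immutable
(every algorithm writes only into missing cells), and any column that
contains a missing cell must hold at least two observed cells, because
estimating that column requires a line. Wine age is a view of the year,
`age = analysis_year − year`, with `analysis_year = 2010` (all
benchmark samples were assayed in June 2010).

## The iterative fill

Step 0 fits, per column, an ordinary least-squares line of outcome
against year on the observed cells only and writes the line value into
each missing cell. Each subsequent cycle then performs, in order:

1. expected table from the current margins,
   `E_ij = row_i · col_j / total`;
2. `X² = Σ (O − E)² / E`;
3. missing cells ← expected values;
4. per-column line refit;
5. missing cells ← refitted line values;

and stops when `|X²_k − X²_{k−1}|` < tolerance (default `1e-4`,
`max_iterations` 10 000 as a safety net — non-convergence is reported
via `stop_reason`, not raised). X² here is a discrepancy measure on
continuous percentages, not a count statistic; p-values attached to it
are informational. The iteration index of the smallest X² is recorded
separately from the stopping index because the trajectory is not
monotone: the fixed points of the line-fill and of the expected-fill do
not coincide, and the alternation can pass its best compromise before
the increments die out.

### Open choices and how they were resolved

The five-step cycle leaves four choices genuinely open. All are
exposed on `ImputerConfig` and enumerated by `search_variants`, which
runs every combination on the benchmark table and ranks the variants by
the largest absolute deviation of their converged solution from the
published reference matrices:

| choice | options | shipped default |
|---|---|---|
| cells entering X² | all 15 / the 7 observed | observed |
| data feeding the refit | filled column / observed cells only | filled |
| working precision | full float / round to 2 decimals | 2 decimals |
| stopping test | end of cycle / right after X² | end of cycle |

The defaults are the unique variant that reproduces the published
solution: every filled cell within ±0.01, every expected cell within
±0.02, stop at iteration 59 (1-based), local minimum at iteration 7.
The two-decimal working precision — every value written into the table
and every expected value entering X² is rounded to 0.01 — models an
original analysis carried out at the printed precision of the table;
at full float precision the same variant stops at iteration 87 with
cells off by up to 0.2. Refitting on observed cells only makes the
iteration stationary after the first cycle and is kept only as a
comparison variant. A table with no missing cells short-circuits to a
single evaluation cycle.

One cell of the published expected matrix, (2002, TMI) = 60.33, is
inconsistent with the margin identity: recomputing
`row_2002 · col_TMI / total` from the published filled table gives
60.63, while every other cell satisfies the identity to within 0.01.
The packaged reference carries the margin-consistent 60.63, treating
the 60.33 as a transcription error.

## Regression diagnostics

With-intercept OLS uses the textbook simple-regression formulas:
`se(b) = s/√Sxx`, 95% half-widths `t_{0.975, n−2} · se`, adjusted
`r²_adj = 1 − (1−r²)(n−1)/(n−2)`, and `F = t_slope²`. A two-point fit
interpolates exactly and carries no inference fields.

For the through-origin line (`slope = Σxy/Σx²`, `s² = SSE/(n−1)`) the
r² convention is deliberately non-standard: the *centered* definition
`1 − SSE/Syy` (clipped at zero) with the adjustment factor `n/(n−2)`.
This is the only pairing that reproduces the benchmark's printed
diagnostics (r = 0.77 ≈ 0.8, r²_adj = 0.43 at n = 7); the conventional
uncentered definition is available behind the `uncentered_r2` flag.
statsmodels is used in the test suite as an independent oracle for
slopes, standard errors and F on random data — never as the
implementation.

## Case study

The benchmark analysis (`censtab.wine_analysis`) chains: the 2×2
subgroup independence check that licenses the expected-value model
(X² = 0.03, p = 0.86); pooled fits on the 7 observed cells vs year, vs
age, and through the origin vs age; the iterative fill; per-source fits
on the columns of the converged *expected* table; an all-data fit on
the 15 observed/estimated cells; pairwise 95%-CI overlap checks on the
per-source coefficients; and the variance decomposition. The total
(200.5), age-explained (114.1) and experimental-error (64.6) variances
are published inputs that are not derivable from the printed table
alone (no standard variance convention on the 15 cells reproduces
200.5); the decomposition is therefore pure arithmetic on them — the
remainder, 21.8 ≈ 11% of the total, is attributed to the wine source —
and is labeled as such in the report.

Known printed-value discrepancies not asserted anywhere: the all-data
fit's CI half-width (±1.75 printed vs ±1.91 recomputed from the printed
cells) and its r (0.77 vs 0.75), both consistent with the original
analysis using unrounded internal values upstream of its printout.

## Synthetic generator

`GeneratorSpec` emulates the benchmark's structure: per-source lines in
the year plus i.i.d. Gaussian noise, masked by either an explicit
censoring pattern (default: the benchmark's 8-of-15 pattern) or a
random mask constrained to keep every censored column at two observed
cells. Defaults are the benchmark conditions: the five vintages, three
sources with the full-precision per-source lines of the converged
solution (the rounded published coefficient pairs would produce
negative outcomes at the latest vintages), and `noise_sd = 2.0` — a
modest measurement error of about two AC points, small against the
30–85% range of the outcome. A single seeded `numpy` generator is
threaded through; no global random state.

For exact recovery oracles the truth must be a fixed point of the
algorithm: simultaneously column-linear and independence-consistent.
`independence_consistent=True` projects the line matrix onto the
rank-one matrix `row_sums × col_sums / total`; the projected columns
remain linear in the year (the row sums are linear), so both fill rules
agree and the noiseless table is recovered to machine precision —
`recovery_study` therefore defaults to the full-precision imputer
configuration rather than the printed-precision benchmark default.

What the generator does **not** model: assay-specific error structure,
between-bottle variation, informative censoring, or non-linear ageing.
Passing recovery tests certify the algorithm's behaviour under its own
assumptions, not its accuracy on arbitrary real tables.

Recovery-study sizes used in the tests: 200 replicates per noise level
over the grid 0–2 AC points, where line extrapolation stays safely
positive; larger noise makes extrapolated cells occasionally
nonpositive, which the expected-value model rejects by design.

## Numerical notes

- No randomness anywhere in the core algorithm; identical input and
  configuration give a bit-identical trace.
- Margin consistency is asserted at relative tolerance 1e−9; X² and
  expected-value computations require strictly positive cells and
  margins, and violations abort with diagnostics rather than produce
  NaNs.
- Rounding in the printed-precision mode uses numpy's `round`
  (half-to-even); on the benchmark trajectory the half-up alternative
  yields identical results.
- The per-column line fit inside the iteration uses the closed normal
  equations and agrees with `fit_ols` to machine precision (asserted in
  the test suite via the shared code path for the initial fill).
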