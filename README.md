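# censtab

Iterative estimation of missing cells in two-way tables of a continuous
outcome, built around a red-wine antioxidant benchmark.

## The problem

A common design in food chemistry and epidemiology crosses an ordinal
factor (production year, age group) with a categorical one (source,
site) and records a continuous outcome in each cell — here the
antioxidant content AC (%) of red wines, measured as the relative drop
of a free-radical EPR signal. Sampling is rarely complete: the
benchmark table has five vintages (1995–2005) × three sources (two
Cabernet Sauvignons and a Merlot from two Romanian vineyards) but only
7 of 15 cells were ever assayed. Margins, expected values and any
whole-table analysis are undefined until the gaps are filled.

`censtab` fills them with a deterministic fixed-point scheme that
exploits two pieces of structure at once:

1. **linear calibration** — within each column *j*, the outcome is
   linear in the year: `AC ≈ a_j · Year + b_j`;
2. **independence** — the table is compatible with row × column
   independence, so each cell should be near its expected value
   `E_ij = (Σ_row i · Σ_col j) / Σ`.

Starting from per-column lines fitted on the observed cells, the
algorithm repeats: compute the expected table from the current margins;
compute `X² = Σ (O − E)²/E`; overwrite the missing cells with their
expected values; refit each column's line; overwrite the missing cells
with the line values — until two consecutive X² values differ by less
than a tolerance (default `1e-4`). Observed cells are never modified.
The X² trajectory is not monotone: on the benchmark it reaches a local
minimum at iteration 7, rises slightly, and triggers the stopping rule
at iteration 59.

Around the core the package provides the complete analysis toolkit the
benchmark study needs: simple OLS and through-origin regression with
the full diagnostic set (r, adjusted r², F, per-coefficient t and 95%
CIs), chi-square expected tables and independence checks, a variance
decomposition, a synthetic-table generator for parameter-recovery
studies, and a variant-search harness that resolves the algorithmic
choices the step list leaves open (see `docs/methods.md`).

## Worked example

Impute the packaged benchmark table from the command line:

```sh
censtab impute --input src/censtab/data/wine.csv \
    --output filled.csv --report report.json
```

prints

```
tolerance reached after 59 iterations (min X² 6.1316 at iteration 7; final X² 6.7232)
```

and `filled.csv` holds the completed table (observed cells unchanged,
estimated cells filled):

```
year,CSI,CSII,TMI
1995,57.82,70.01,84.05
2000,42.04,69.54,64.02
2002,50.0,53.73,56.01
2003,27.98,50.53,56.56
2005,18.86,44.13,35.8
```

The same run from Python, plus the pooled calibration on the seven
observed cells:

```python
import censtab

table = censtab.load_wine_table()

fit = censtab.pooled_regressions(table)["year"]
# AC (%) = 9215(±8038) − 4.58(±4.02)·Year,  F = 8.6, p_F = 0.03
print(f"slope {fit.slope:.2f} ± {fit.ci95_slope:.2f}, F {fit.f_value:.1f}")

result = censtab.iterate(table)
print(result.n_iterations)              # 59
print(result.argmin_iteration)          # 7
print(result.filled_table.values[0, 0]) # 57.82  (CSI @ 1995, %)
```

The negative year slope (−4.58 % per vintage year) says older wines
carry more antioxidants; equivalently, AC grows by the same amount per
year of wine age. `censtab analyze-wine --out-dir out/` writes the full
case-study report: all regressions, the subgroup independence check
(X² = 0.03, p = 0.86), the X² trace, and the variance decomposition
attributing 11% of the total variance to the wine source.

Synthetic data with the same structure (for recovery studies):

```sh
censtab simulate --replicates 200 --seed 1 --out sim/
```

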