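"""Synthetic censored tables with the structure the method assumes.

The generator emulates the benchmark wine table: a handful of vintage
years, a few sources, a per-source linear trend of the outcome in the
year, additive Gaussian measurement noise, and a censoring mask that
hides some cells while leaving every column at least two observed
points.  It exists for property tests and parameter-recovery studies,
not for realism: there is no assay-specific error structure, no
between-bottle variation, and the censoring is a fixed or uniformly
random mask rather than anything informative.

For exact zero-noise recovery oracles the underlying truth must be a
fixed point of the algorithm, i.e. simultaneously column-linear and
consistent with row x column independence.  ``independence_consistent``
projects the line-generated matrix onto that manifold (the rank-one
matrix ``row_sums x col_sums / total``, whose columns remain linear in
the year because the row sums are).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imputer import ImputerConfig, iterate
from .table_model import CensoredTable

__all__ = ["GeneratorSpec", "generate", "recovery_study", "RecoveryStudyResult"]

#: the benchmark table's censoring pattern (True = observed)
WINE_MASK = np.array(
    [
        [False, True, False],
        [False, True, False],
        [True, False, False],
        [True, False, True],
        [True, False, True],
    ]
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic censored table.

    Defaults mirror the benchmark wine study: five vintages, three
    sources with per-source year trends matching the published
    per-source lines, a couple of AC-percent points of measurement
    noise, and the benchmark censoring pattern (8 of 15 cells hidden).
    """

    years: tuple[int, ...] = (1995, 2000, 2002, 2003, 2005)
    sources: tuple[str, ...] = ("CSI", "CSII", "TMI")
    # per-source lines of the benchmark solution at full precision (the
    # rounded published pairs would go negative at the latest vintages)
    slopes: tuple[float, ...] = (-2.701, -3.953, -4.070)
    intercepts: tuple[float, ...] = (5444.1, 7968.1, 8203.4)
    noise_sd: float = 2.0
    censoring_mask: np.ndarray | None = field(default=None)
    missing_fraction: float | None = None
    seed: int = 0
    independence_consistent: bool = False

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.sources) or len(self.intercepts) != len(
            self.sources
        ):
            raise ValueError("one slope and intercept per source is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.censoring_mask is None and self.missing_fraction is None:
            object.__setattr__(self, "censoring_mask", WINE_MASK.copy())
        if self.censoring_mask is not None:
            mask = np.asarray(self.censoring_mask, dtype=bool)
            if mask.shape != (len(self.years), len(self.sources)):
                raise ValueError("censoring_mask shape must match years x sources")
            object.__setattr__(self, "censoring_mask", mask)
        elif not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.years), len(self.sources)


def _truth_matrix(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    years = np.asarray(spec.years, dtype=float)
    lines = np.empty(spec.shape)
    for j, (s, b) in enumerate(zip(spec.slopes, spec.intercepts)):
        lines[:, j] = s * years + b
    if spec.independence_consistent:
        # rank-one projection: exactly independence-consistent, columns
        # stay linear in the year because the row sums are
        total = lines.sum()
        lines = np.outer(lines.sum(axis=1), lines.sum(axis=0)) / total
    if spec.noise_sd > 0:
        lines = lines + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return lines


def _draw_mask(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.censoring_mask is not None:
        mask = spec.censoring_mask
        if np.any((~mask).any(axis=0) & (mask.sum(axis=0) < 2)):
            raise ValueError("censoring_mask strands a column below 2 observed cells")
        return mask.copy()
    n_rows, n_cols = spec.shape
    n_hide = int(round(spec.missing_fraction * n_rows * n_cols))
    for _ in range(1000):
        flat = np.ones(n_rows * n_cols, dtype=bool)
        flat[rng.choice(flat.size, size=n_hide, replace=False)] = False
        mask = flat.reshape(spec.shape)
        miss = ~mask
        if np.all(~miss.any(axis=0) | (mask.sum(axis=0) >= 2)):
            return mask
    raise ValueError(
        "could not draw a censoring mask keeping every censored column "
        "at 2 observed cells; lower missing_fraction"
    )


def generate(spec: GeneratorSpec) -> tuple[CensoredTable, np.ndarray]:
    """Draw one censored table and return it with the full truth matrix.

    Deterministic under ``spec.seed``: the same spec always yields the
    same table.  The truth matrix includes the noise; masked cells of
    the table are exactly the hidden truth values.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_matrix(spec, rng)
    mask = _draw_mask(spec, rng)
    table = CensoredTable(spec.years, spec.sources, truth, mask)
    return table, truth


@dataclass(frozen=True)
class RecoveryStudyResult:
    """Error of imputed values against the truth over replicates."""

    bias: np.ndarray  # mean (imputed - truth) per cell, NaN where never masked
    rmse: np.ndarray  # root-mean-square error per cell, NaN where never masked
    overall_rmse: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias.tolist(),
            "rmse": self.rmse.tolist(),
            "overall_rmse": self.overall_rmse,
            "n_replicates": self.n_replicates,
        }


def recovery_study(
    spec: GeneratorSpec,
    replicates: int = 1,
    config: ImputerConfig | None = None,
) -> RecoveryStudyResult:
    """Generate-and-impute *replicates* times; aggregate imputation error.

    Each replicate reseeds the generator with ``spec.seed + k`` so the
    whole study is reproducible from the spec alone.  The default
    imputer configuration works at full float precision (no printed-
    precision rounding), which is what the zero-noise exactness oracle
    requires.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if config is None:
        config = ImputerConfig(round_to=None)
    shape = spec.shape
    sq_err = np.zeros(shape)
    err_sum = np.zeros(shape)
    n_masked = np.zeros(shape)
    for k in range(replicates):
        rep = replace(spec, seed=spec.seed + k)
        table, truth = generate(rep)
        result = iterate(table, config)
        miss = ~table.observed_mask
        diff = result.filled_table.values - truth
        sq_err[miss] += diff[miss] ** 2
        err_sum[miss] += diff[miss]
        n_masked[miss] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(n_masked > 0, err_sum / n_masked, np.nan)
        rmse = np.where(n_masked > 0, np.sqrt(sq_err / n_masked), np.nan)
    total_masked = n_masked.sum()
    overall = float(np.sqrt(sq_err.sum() / total_masked)) if total_masked else 0.0
    return RecoveryStudyResult(
        bias=bias, rmse=rmse, overall_rmse=overall, n_replicates=replicates
    )
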