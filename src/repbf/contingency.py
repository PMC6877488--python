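"""Default Bayes factor for independence in a 2x2 contingency table.

Sampling scheme: independent multinomial with row totals fixed — each row
is a binomial/multinomial draw over the columns.  Under H1 every row has its
own column-probability vector with a symmetric Dirichlet(a) prior; under H0
the rows share a single column-probability vector, again with a symmetric
Dirichlet(a) prior.  Both marginal likelihoods are Dirichlet-multinomial
closed forms evaluated with log-gamma arithmetic, so the Bayes factor is
exact up to floating point.  A classical Pearson chi-square (no continuity
correction) is provided for parity reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .result import BayesFactorResult


@dataclass(frozen=True)
class CrossTable:
    """A 2x2 count table with row/column labels and a sampling scheme tag."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")
    fixed_margin: str = "rows"

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError(f"counts must be 2x2, got shape {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if self.fixed_margin not in ("rows", "columns", "none"):
            raise ValueError(f"unknown margin scheme {self.fixed_margin!r}")
        # normalize to nested tuples so the dataclass stays hashable
        object.__setattr__(self, "counts", tuple(tuple(int(v) for v in row) for row in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class DirichletPrior:
    """Symmetric Dirichlet concentration applied per cell-probability vector."""

    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def _log_dirichlet_multinomial(counts: np.ndarray, a: float) -> float:
    """Log marginal of a multinomial vector under a symmetric Dirichlet(a).

    Includes the multinomial coefficient, so this is a proper log
    prior-predictive mass.
    """
    n = counts.sum()
    j = counts.size
    log_coef = gammaln(n + 1) - gammaln(counts + 1).sum()
    log_beta_ratio = (
        gammaln(j * a) - j * gammaln(a) + gammaln(counts + a).sum() - gammaln(n + j * a)
    )
    return float(log_coef + log_beta_ratio)


def bf10_contingency(
    table: CrossTable, prior: DirichletPrior | None = None
) -> BayesFactorResult:
    """Bayes factor against independence for a rows-fixed 2x2 table.

    H1: each row's column probabilities get an independent symmetric
    Dirichlet(a) prior; H0: both rows share one Dirichlet(a)-distributed
    probability vector.
    """
    if prior is None:
        prior = DirichletPrior()
    if table.fixed_margin != "rows":
        raise NotImplementedError(
            f"sampling scheme {table.fixed_margin!r} is not implemented; "
            "only independent multinomial sampling with row totals fixed is supported"
        )
    arr = table.array
    a = prior.concentration
    m1 = sum(_log_dirichlet_multinomial(arr[i], a) for i in range(2))
    # Under H0 the two rows are conditionally iid given the shared vector:
    # the marginal is the Dirichlet-multinomial of the column totals times
    # the product of within-row multinomial coefficients over the pooled one.
    col = arr.sum(axis=0)
    m0 = _log_dirichlet_multinomial(col, a)
    m0 += sum(
        float(gammaln(arr[i].sum() + 1) - gammaln(arr[i] + 1).sum()) for i in range(2)
    ) - float(gammaln(col.sum() + 1) - gammaln(col + 1).sum())
    return BayesFactorResult(
        log_bf10=m1 - m0,
        marginal_h1=m1,
        marginal_h0=m0,
        hypothesis_labels=(
            f"independence, shared Dirichlet({a:g})",
            f"row-wise Dirichlet({a:g})",
        ),
        method="closed_form",
    )


def pool_tables(t_orig: CrossTable, t_rep: CrossTable) -> CrossTable:
    """Element-wise sum of two tables; labels and scheme must match.

    Pooling presumes the two studies' observations are exchangeable (a
    direct, close replication); mismatched labels are treated as evidence
    they are not.
    """
    if t_orig.row_labels != t_rep.row_labels or t_orig.col_labels != t_rep.col_labels:
        raise ValueError(
            f"label mismatch: {t_orig.row_labels}x{t_orig.col_labels} vs "
            f"{t_rep.row_labels}x{t_rep.col_labels}"
        )
    if t_orig.fixed_margin != t_rep.fixed_margin:
        raise ValueError("margin schemes differ; tables are not poolable")
    summed = t_orig.array + t_rep.array
    return CrossTable(
        counts=tuple(tuple(int(v) for v in row) for row in summed),
        row_labels=t_orig.row_labels,
        col_labels=t_orig.col_labels,
        fixed_margin=t_orig.fixed_margin,
    )


def pearson_chi_square(table: CrossTable) -> tuple[float, int]:
    """Pearson chi-square statistic and df, without continuity correction."""
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row or column margin; expected counts undefined")
    stat, _, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof)
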