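"""Classical cohort-comparison statistics and rater-agreement ICC.

Covers the demographic-table tests (two-sided Fisher exact for 2x2,
Freeman-Halton exact test for r x c, t-test/one-way ANOVA for continuous
variables) and the two-way random-effects, absolute-agreement, single-rater
intraclass correlation ICC(2,1) used to screen feature stability between
raters.

The two-sided Fisher p-value follows the probability-mass convention: the
sum of the probabilities of all margin-consistent tables no more probable
than the observed one (with a 1e-7 relative slack for floating-point ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, exp

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "fisher_exact_2x2",
    "fisher_freeman_halton",
    "group_mean_test",
    "icc_agreement",
]

_REL_SLACK = 1e-7
_ENUMERATION_BOUND = 500


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("table must be 2-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


def _as_counts(table: ContingencyTable | np.ndarray) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError(f"fisher_exact_2x2 needs a 2x2 table, got {counts.shape}")
    # scipy's two-sided Fisher uses the same probability-mass convention
    return float(sps.fisher_exact(counts, alternative="two-sided")[1])


def _log_table_prob(counts: np.ndarray, log_margin_term: float) -> float:
    return log_margin_term - sum(lgamma(x + 1) for x in counts.ravel())


def _enumerate_tables(row_sums: np.ndarray, col_sums: np.ndarray):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill_row(i: int, col_rem: np.ndarray, rows: list[list[int]]):
        if i == r - 1:
            if (col_rem >= 0).all() and col_rem.sum() == row_sums[i]:
                yield np.array(rows + [list(col_rem)])
            return
        def fill_cell(j: int, rem: int, row: list[int]):
            if j == c - 1:
                if 0 <= rem <= col_rem[j]:
                    yield row + [rem]
                return
            for v in range(min(rem, col_rem[j]) + 1):
                yield from fill_cell(j + 1, rem - v, row + [v])
        for row in fill_cell(0, int(row_sums[i]), []):
            yield from fill_row(i + 1, col_rem - np.array(row), rows + [row])

    yield from fill_row(0, col_sums.copy(), [])


def fisher_freeman_halton(table: ContingencyTable | np.ndarray) -> float:
    """Exact conditional (Freeman-Halton) two-sided p for an r x c table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table.  A 2x2
    input reduces exactly to :func:`fisher_exact_2x2`.  Bounded to tables
    with total <= 500; larger inputs raise (a Monte-Carlo approximation
    would be needed beyond that).
    """
    counts = _as_counts(table)
    n = int(counts.sum())
    if n > _ENUMERATION_BOUND:
        raise ValueError(
            f"table total {n} exceeds the enumeration bound {_ENUMERATION_BOUND}; "
            "use a Monte-Carlo approximation for larger tables"
        )
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if min(counts.shape) == 1:
        return 1.0  # single margin-consistent table
    log_margin = (
        sum(lgamma(x + 1) for x in row_sums)
        + sum(lgamma(x + 1) for x in col_sums)
        - lgamma(n + 1)
    )
    lp_obs = _log_table_prob(counts, log_margin)
    cutoff = lp_obs + np.log1p(_REL_SLACK)
    p = 0.0
    for t in _enumerate_tables(row_sums, col_sums):
        lp = _log_table_prob(t, log_margin)
        if lp <= cutoff:
            p += exp(lp)
    return min(p, 1.0)


def group_mean_test(
    samples_by_group: dict[str, np.ndarray] | list[np.ndarray],
    equal_var: bool = True,
) -> float:
    """Two-sided p for a difference in group means.

    Two groups: independent-samples t-test (pooled variance by default,
    Welch with ``equal_var=False``).  Three or more groups: one-way ANOVA
    F-test.
    """
    if isinstance(samples_by_group, dict):
        groups = [np.asarray(g, dtype=float) for g in samples_by_group.values()]
    else:
        groups = [np.asarray(g, dtype=float) for g in samples_by_group]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    if all(g.var() == 0 for g in groups):
        if len({float(g.mean()) for g in groups}) == 1:
            raise ValueError("all observations identical; test undefined")
    if len(groups) == 2:
        return float(sps.ttest_ind(groups[0], groups[1], equal_var=equal_var).pvalue)
    return float(sps.f_oneway(*groups).pvalue)


def icc_agreement(ratings_a: np.ndarray, ratings_b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    With n items and k = 2 raters, from the two-way ANOVA mean squares
    (rows = items MSR, columns = raters MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 items")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise ValueError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)
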