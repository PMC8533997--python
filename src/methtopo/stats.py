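"""The nonparametric comparison battery.

Rank tests (Mann–Whitney U, Kruskal–Wallis H), Spearman correlation and the
Welch t-test on M-value aggregates are delegated to scipy.stats behind a
uniform :class:`TestResult` surface that also carries the Bonferroni divisor
used for significance flagging (strict ``p < 0.05/m``).

The Freeman–Halton exact test of independence for r x c contingency tables —
the generalization of Fisher's exact test — is implemented here by full
recursive enumeration of all tables sharing the observed margins, with
log-factorial arithmetic.  The two-sided p-value follows the classical
point-probability rule: the sum of the multivariate hypergeometric
probabilities of every table as probable or less probable than the observed
one (probability ties resolved with relative tolerance 1e-7).  Each call
verifies that the enumerated probabilities sum to 1 within 1e-9.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "TestResult",
    "RxCTable",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman",
    "welch_t",
    "welch_t_on_m",
    "freeman_halton_exact",
    "bonferroni_report",
]

ALPHA = 0.05
_TIE_RTOL = 1e-7  # relative tolerance for "as probable or less" comparisons
DEFAULT_TABLE_BUDGET = 50_000_000


@dataclass(frozen=True)
class TestResult:
    """One test outcome with its multiple-testing context."""

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    bonferroni_m: int = 1

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.bonferroni_m < 1:
            raise ValidationError("bonferroni_m must be >= 1")

    @property
    def threshold(self) -> float:
        return ALPHA / self.bonferroni_m

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold


@dataclass(frozen=True)
class RxCTable:
    """A non-negative integer contingency table with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = field(default=())
    col_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.floor(arr)):
            raise ValidationError("contingency table entries must be non-negative integers")
        object.__setattr__(self, "counts", arr.astype(np.int64))


def _check_samples(*samples):
    for s in samples:
        if len(s) == 0:
            raise ValidationError("empty sample passed to a rank test")


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    The exact null distribution (by enumeration over rank assignments) is
    used when the pooled size is at most 20 and there are no ties; otherwise
    the normal approximation with tie correction and continuity correction.
    The method tag records which path ran.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_samples(x, y)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if np.all(pooled == pooled[0]):
        # fully degenerate: distributions identical by construction
        return TestResult(len(x) * len(y) / 2.0, 1.0,
                          "mann-whitney-degenerate", (len(x), len(y)))
    if len(pooled) <= 20 and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        tag = "mann-whitney-exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        tag = "mann-whitney-normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), tag,
                      (len(x), len(y)))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from chi-square with k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis needs at least 2 groups")
    _check_samples(*groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(len(g) for g in groups))
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis",
                      tuple(len(g) for g in groups))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties; t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("spearman needs paired samples of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("spearman correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "spearman", (len(x),))


def welch_t(x, y) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "welch-t-degenerate", (len(x), len(y)))
        return TestResult(math.copysign(math.inf, x.mean() - y.mean()), 0.0,
                          "welch-t-degenerate", (len(x), len(y)))
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch-t",
                      (len(x), len(y)))


def welch_t_on_m(mvalues, groups) -> dict[str, TestResult]:
    """Welch t per region class on M-value score aggregates.

    ``mvalues`` is a samples x classes table (a :class:`~methtopo.containers.
    ScoreTable` on the M scale or a DataFrame); ``groups`` is a boolean or
    two-level label vector aligned with its samples.
    """
    import pandas as pd

    frame = mvalues.to_frame() if hasattr(mvalues, "to_frame") else pd.DataFrame(mvalues)
    labels = np.asarray(groups)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValidationError("welch_t_on_m requires exactly two groups")
    out = {}
    for cls_name in frame.columns:
        v = frame[cls_name].to_numpy(float)
        out[str(cls_name)] = welch_t(v[labels == levels[0]], v[labels == levels[1]])
    return out


# ---------------------------------------------------------------------------
# Freeman–Halton exact test


def _count_bound(row_sums, c) -> float:
    """Upper bound on the number of tables with the given margins."""
    return float(np.prod([math.comb(int(r) + c - 1, c - 1) for r in row_sums]))


def freeman_halton_exact(table, budget: int = DEFAULT_TABLE_BUDGET) -> TestResult:
    """Exact test of independence for an r x c table (Freeman–Halton).

    Enumerates every table with the observed margins; the statistic reported
    is the observed table's point probability under the multivariate
    hypergeometric null.  Zero row/column margins make the table degenerate
    (p = 1, with a warning).  Tables whose margin structure admits more than
    ``budget`` candidate tables raise instead of silently approximating.
    """
    if isinstance(table, RxCTable):
        counts = table.counts
    else:
        counts = RxCTable(np.asarray(table)).counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    keep_r = row_sums > 0
    keep_c = col_sums > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("zero margin in contingency table; dropping degenerate lanes",
                      stacklevel=2)
        counts = counts[keep_r][:, keep_c]
        row_sums = counts.sum(axis=1)
        col_sums = counts.sum(axis=0)
    r, c = counts.shape
    n = int(counts.sum())
    if r < 2 or c < 2:
        warnings.warn("degenerate contingency table (fewer than 2 informative "
                      "rows/columns); p = 1", stacklevel=2)
        return TestResult(1.0, 1.0, "freeman-halton-degenerate", (n,))
    if _count_bound(row_sums, c) > budget:
        raise ValidationError(
            f"margin structure admits more than {budget} tables; enumeration refused"
        )

    lgam = [math.lgamma(k + 1) for k in range(n + 1)]
    log_const = (
        sum(lgam[int(k)] for k in row_sums)
        + sum(lgam[int(k)] for k in col_sums)
        - lgam[n]
    )

    def log_prob(cells_lgam_sum: float) -> float:
        return log_const - cells_lgam_sum

    obs_cells = float(sum(lgam[int(v)] for v in counts.ravel()))
    log_p_obs = log_prob(obs_cells)
    tie_slack = math.log1p(_TIE_RTOL)

    row_sums = [int(v) for v in row_sums]
    col_rem = [int(v) for v in col_sums]
    total_prob = 0.0
    tail_prob = 0.0

    # Enumerate tables row by row; within a row, fill cells left to right.
    # State: (row index, cell index, remainder of current row, lgamma sum so far).
    def rec_row(i: int, cell_sum: float):
        nonlocal total_prob, tail_prob
        if i == r - 1:
            # last row forced by column remainders
            s = cell_sum
            for v in col_rem:
                s += lgam[v]
            lp = log_prob(s)
            p = math.exp(lp)
            total_prob += p
            if lp <= log_p_obs + tie_slack:
                tail_prob += p
            return
        fill_cells(i, 0, row_sums[i], cell_sum)

    def fill_cells(i: int, j: int, rem: int, cell_sum: float):
        if j == c - 1:
            if rem <= col_rem[j]:
                col_rem[j] -= rem
                rec_row(i + 1, cell_sum + lgam[rem])
                col_rem[j] += rem
            return
        # remaining cells in this row must be able to absorb the remainder
        hi = min(rem, col_rem[j])
        for v in range(hi + 1):
            col_rem[j] -= v
            fill_cells(i, j + 1, rem - v, cell_sum + lgam[v])
            col_rem[j] += v

    rec_row(0, 0.0)

    if abs(total_prob - 1.0) > 1e-9:
        raise RuntimeError(
            f"enumeration normalization check failed: probabilities sum to {total_prob!r}"
        )
    return TestResult(math.exp(log_p_obs), min(tail_prob, 1.0),
                      "freeman-halton-exact", (n,))


def bonferroni_report(results, m: int):
    """Annotate results with a shared Bonferroni divisor.

    Accepts a list of :class:`TestResult` (returns a new list) or a dict
    mapping labels to results (returns a new dict).  Significance is strict:
    ``p < 0.05/m``.
    """
    if m < 1:
        raise ValidationError("Bonferroni divisor must be >= 1")
    if isinstance(results, dict):
        return {k: replace(v, bonferroni_m=m) for k, v in results.items()}
    return [replace(res, bonferroni_m=m) for res in results]
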