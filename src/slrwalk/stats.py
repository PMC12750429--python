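"""Between-group descriptive statistics and the correlation screen.

Categorical group ratios (sex, impairment-scale grades) are compared with
the Fisher exact test, generalized to r x c tables by the Freeman-Halton
rule: the two-sided p-value is the total probability, under fixed
margins, of every table no more probable than the observed one.  The
enumeration is exact (rational arithmetic), which is feasible at the
cohort sizes this package targets.

Continuous variables are dispatched to the pooled-variance unpaired t
test when both groups pass a Shapiro-Wilk normality check and a
median-centered Levene homogeneity check (alpha .05 each), and to the
Mann-Whitney U test otherwise.  The correlation screen computes pairwise
Pearson coefficients with two-tailed p-values and flags significance at
alpha .05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sst

ALPHA = 0.05


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("negative cell count")


@dataclass
class GroupComparisonResult:
    variable: str
    test: str            # "t" | "mann_whitney" | "fisher"
    statistic: float
    p_value: float
    n_per_group: tuple[int, int] = (0, 0)
    note: str = ""


def _table_prob(rows: list[int], cols: list[int], flat: list[int]) -> Fraction:
    n = sum(rows)
    num = math.prod(math.factorial(x) for x in rows) * math.prod(math.factorial(x) for x in cols)
    den = math.factorial(n) * math.prod(math.factorial(x) for x in flat)
    return Fraction(num, den)


def _enumerate_tables(rows: list[int], cols: list[int]):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(rows), len(cols)

    def fill(row_idx: int, col_remaining: list[int], acc: list[int]):
        if row_idx == r - 1:
            if all(v >= 0 for v in col_remaining):
                yield acc + col_remaining
            return
        target = rows[row_idx]
        # enumerate this row's first c-1 cells; last cell is forced
        ranges = [range(min(target, col_remaining[j]) + 1) for j in range(c - 1)]
        for cells in product(*ranges):
            s = sum(cells)
            last = target - s
            if last < 0 or last > col_remaining[c - 1]:
                continue
            new_remaining = [col_remaining[j] - cells[j] for j in range(c - 1)]
            new_remaining.append(col_remaining[c - 1] - last)
            yield from fill(row_idx + 1, new_remaining, acc + list(cells) + [last])

    yield from fill(0, list(cols), [])


def fisher_exact(table: ContingencyTable | np.ndarray | list) -> float:
    """Two-sided Fisher exact p-value for an r x c contingency table.

    For 2x2 tables this is the classic rule (sum of hypergeometric
    probabilities no larger than the observed table's); for larger tables
    it is the Freeman-Halton generalization by full enumeration of the
    margin-constrained tables.  All arithmetic is exact rational, so the
    result is correct to float conversion.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    rows = counts.sum(axis=1).tolist()
    cols = counts.sum(axis=0).tolist()
    if min(rows) == 0 or min(cols) == 0:
        raise ValueError("degenerate table: a row or column margin is zero")
    flat = counts.flatten().tolist()
    p_obs = _table_prob(rows, cols, flat)
    total = Fraction(0)
    for t in _enumerate_tables(rows, cols):
        p = _table_prob(rows, cols, t)
        if p <= p_obs:
            total += p
    return float(total)


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    variable: str = "",
    kind: str = "continuous",
    alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Two-group comparison with the test-dispatch rule described above.

    ``kind='continuous'``: Shapiro-Wilk per group plus median-centered
    Levene decide pooled t vs Mann-Whitney (exact U distribution when both
    groups have 12 or fewer untied observations, tie-corrected normal
    approximation otherwise).  ``kind='categorical'``: the inputs are
    category codes and the comparison is the Fisher exact test on the
    crossed counts.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if kind == "categorical":
        levels = sorted(set(a.tolist()) | set(b.tolist()))
        if len(levels) < 2:
            return GroupComparisonResult(variable, "fisher", float("nan"), 1.0,
                                         (len(a), len(b)), note="single category level")
        counts = np.array([
            [int(np.sum(a == lv)) for lv in levels],
            [int(np.sum(b == lv)) for lv in levels],
        ])
        p = fisher_exact(counts)
        return GroupComparisonResult(variable, "fisher", float("nan"), p, (len(a), len(b)))

    a = a[~np.isnan(a.astype(float))].astype(float)
    b = b[~np.isnan(b.astype(float))].astype(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"{variable or 'variable'}: need at least 2 observations per group")
    normal = True
    for x in (a, b):
        if len(x) >= 3 and np.ptp(x) > 0:
            normal = normal and sst.shapiro(x).pvalue > alpha
    if np.ptp(a) > 0 or np.ptp(b) > 0:
        homogeneous = sst.levene(a, b, center="median").pvalue > alpha
    else:
        homogeneous = True
    if normal and homogeneous:
        res = sst.ttest_ind(a, b, equal_var=True)
        return GroupComparisonResult(variable, "t", float(res.statistic), float(res.pvalue), (len(a), len(b)))
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 12 and not ties) else "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(
        variable, "mann_whitney", float(res.statistic), float(res.pvalue),
        (len(a), len(b)), note=f"U p-value via {method} method",
    )


@dataclass
class CorrelationScreen:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean at alpha .05
    excluded: list[str]        # zero-variance variables left out

    def is_significant(self, a: str, b: str) -> bool:
        return bool(self.significant.loc[a, b])


def correlation_screen(table: pd.DataFrame, variables: list[str] | None = None,
                       alpha: float = ALPHA) -> CorrelationScreen:
    """Pairwise Pearson correlations with two-tailed p-values.

    Uses pairwise-complete observations; requires at least 3 complete
    pairs.  Zero-variance variables are excluded from pairing and listed
    in ``excluded``.
    """
    if variables is None:
        variables = [c for c in table.columns if table[c].dtype.kind in "fiu"]
    excluded = []
    usable = []
    for v in variables:
        x = table[v].astype(float)
        if np.nanstd(x.to_numpy()) == 0:
            excluded.append(v)
        else:
            usable.append(v)
    k = len(usable)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = table[usable[i]].astype(float).to_numpy()
            y = table[usable[j]].astype(float).to_numpy()
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({usable[i]}, {usable[j]})")
            res = sst.pearsonr(x[mask], y[mask])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=usable, columns=usable)
    pdf = pd.DataFrame(p, index=usable, columns=usable)
    sig = (pdf < alpha) & ~np.eye(k, dtype=bool)
    return CorrelationScreen(usable, rdf, pdf, pd.DataFrame(sig, index=usable, columns=usable), excluded)


def group_comparison_table(
    table: pd.DataFrame,
    label_column: str = "group",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort-description report: one row per variable with test and p-value."""
    groups = sorted(table[label_column].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga = table[table[label_column] == groups[0]]
    gb = table[table[label_column] == groups[1]]
    if continuous is None:
        continuous = [c for c in table.columns
                      if c != label_column and table[c].dtype.kind in "fiu"]
    categorical = categorical or []
    rows = []
    for var in categorical:
        res = compare_groups(ga[var].to_numpy(), gb[var].to_numpy(), var, kind="categorical")
        rows.append({"variable": var, "test": res.test, "statistic": res.statistic,
                     "p_value": res.p_value})
    for var in continuous:
        a = ga[var].astype(float).to_numpy()
        b = gb[var].astype(float).to_numpy()
        try:
            res = compare_groups(a, b, var)
        except ValueError:
            rows.append({"variable": var, "test": "skipped", "statistic": np.nan, "p_value": np.nan})
            continue
        rows.append({"variable": var, "test": res.test, "statistic": res.statistic,
                     "p_value": res.p_value})
    return pd.DataFrame(rows)
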