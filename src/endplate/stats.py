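"""Statistical battery for cohort comparisons.

* :func:`pooled_t_test` — two-sample Student (pooled-variance) t-test from
  group summaries (n, mean, SD), with the 95% CI of the mean difference
  and Cohen's d on the pooled SD.  Pooled rather than Welch: the
  reference tables' printed t and d values follow the pooled formulas.
* :func:`chi_square_cramers_v` — Pearson chi-square (no continuity
  correction) and Cramér's V on an r x c table after removing all-zero
  rows/columns (required to avoid zero expected counts).
* :func:`freeman_halton_exact` — the Freeman–Halton generalization of
  Fisher's exact test to r x c tables: exhaustive enumeration of all
  tables with the observed margins; the two-sided p sums the
  probabilities of tables no more probable than the observed one.
* :func:`icc_absolute_agreement` — ICC(A,1): two-way random effects,
  absolute agreement, single rater, from the ANOVA mean squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import stats as sps

from .errors import EnumerationBudgetError, InputError, ParameterError, \
    UndefinedEffectError


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group of measurements (mm)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError(f"group needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")

    @classmethod
    def from_data(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(len(x), float(x.mean()), float(x.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    cohens_d: float
    mean_diff: float


@dataclass(frozen=True)
class ExactTestResult:
    p_exact: float
    chi2: float
    cramers_v: float
    effective_dims: tuple[int, int]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    var_subjects: float
    var_raters: float
    var_error: float


def pooled_t_test(g1: GroupSummary, g2: GroupSummary,
                  alpha: float = 0.05) -> TTestResult:
    """Student two-sample t-test from summaries, with CI and Cohen's d.

    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2);
    t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2));  d = (m1-m2)/sp;
    CI = (m1-m2) +/- t_{1-alpha/2, df} * SE.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    df = g1.n + g2.n - 2
    diff = g1.mean - g2.mean
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    if sp2 == 0:
        if diff == 0:
            # no variability, no difference: define t = d = 0
            return TTestResult(0.0, df, 1.0, 0.0, 0.0, 0.0, 0.0)
        raise ParameterError("zero pooled variance with non-zero difference")
    sp = math.sqrt(sp2)
    se = sp * math.sqrt(1 / g1.n + 1 / g2.n)
    t = diff / se
    p = float(2 * sps.t.sf(abs(t), df))
    tc = float(sps.t.ppf(1 - alpha / 2, df))
    return TTestResult(t, df, p, diff - tc * se, diff + tc * se, diff / sp, diff)


def _drop_zero_margins(table: np.ndarray):
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    return table[rows][:, cols]


def _as_table(table) -> np.ndarray:
    t = np.asarray(getattr(table, "counts", table))
    if t.ndim != 2:
        raise InputError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.number) or (t < 0).any() or \
            not np.allclose(t, np.round(t)):
        raise InputError("contingency table must hold non-negative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise InputError("contingency table must have a positive total")
    return t


def chi_square_cramers_v(table) -> ExactTestResult:
    """Pearson chi-square and Cramér's V after zero-margin removal.

    V = sqrt(chi2 / (N * (min(r', c') - 1))) on the reduced r' x c'
    table.  Raises :class:`UndefinedEffectError` if fewer than two rows
    or columns remain.
    """
    t = _drop_zero_margins(_as_table(table))
    r, c = t.shape
    if r < 2 or c < 2:
        raise UndefinedEffectError(
            f"effect size undefined on a {r}x{c} table after zero-margin removal"
        )
    chi2 = float(sps.chi2_contingency(t, correction=False)[0])
    n = int(t.sum())
    v = math.sqrt(chi2 / (n * (min(r, c) - 1)))
    return ExactTestResult(float("nan"), chi2, v, (r, c))


def _log_table_prob(t: np.ndarray, log_const: float) -> float:
    return log_const - sum(lgamma(x + 1) for x in t.flat)


def freeman_halton_exact(table, budget_n: int = 200,
                         rel_tol: float = 1e-12) -> float:
    """Two-sided Freeman–Halton exact p for an r x c table.

    Enumerates every table with the observed margins; p is the sum of
    multivariate-hypergeometric probabilities of tables whose probability
    is <= the observed one (with ``rel_tol`` slack on the comparison to
    absorb floating-point ties).  All-zero rows/columns do not affect p.
    """
    t = _drop_zero_margins(_as_table(table))
    n = int(t.sum())
    if n > budget_n:
        raise EnumerationBudgetError(
            f"N = {n} exceeds the enumeration budget of {budget_n}; "
            "use chi_square_cramers_v instead"
        )
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    r, c = t.shape
    if r < 2 or c < 2:
        return 1.0  # a single category is always consistent with its margins
    log_const = (sum(lgamma(x + 1) for x in rows)
                 + sum(lgamma(x + 1) for x in cols) - lgamma(n + 1))
    lp_obs = _log_table_prob(t, log_const)
    log_slack = math.log1p(rel_tol)

    p_val = 0.0
    work = np.empty((r, c), dtype=np.int64)

    def fill_row(ri: int, col_rem: np.ndarray):
        nonlocal p_val
        if ri == r - 1:
            work[ri] = col_rem
            lp = _log_table_prob(work, log_const)
            if lp <= lp_obs + log_slack:
                p_val += math.exp(lp)
            return
        target = int(rows[ri])

        def fill_cell(ci: int, rem: int):
            if ci == c - 1:
                if 0 <= rem <= col_rem[ci]:
                    work[ri, ci] = rem
                    fill_row(ri + 1, col_rem - work[ri])
                return
            for v in range(min(rem, int(col_rem[ci])) + 1):
                work[ri, ci] = v
                fill_cell(ci + 1, rem - v)

        fill_cell(0, target)

    fill_row(0, cols.copy())
    return min(p_val, 1.0)


def enumerate_margin_tables(table):
    """Yield (table, probability) for every table sharing the observed
    margins.  Exposed for diagnostics and property testing."""
    t = _drop_zero_margins(_as_table(table))
    n = int(t.sum())
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    r, c = t.shape
    log_const = (sum(lgamma(x + 1) for x in rows)
                 + sum(lgamma(x + 1) for x in cols) - lgamma(n + 1))
    work = np.empty((r, c), dtype=np.int64)
    out = []

    def fill_row(ri, col_rem):
        if ri == r - 1:
            work[ri] = col_rem
            out.append((work.copy(),
                        math.exp(_log_table_prob(work, log_const))))
            return

        def fill_cell(ci, rem):
            if ci == c - 1:
                if 0 <= rem <= col_rem[ci]:
                    work[ri, ci] = rem
                    fill_row(ri + 1, col_rem - work[ri])
                return
            for v in range(min(rem, int(col_rem[ci])) + 1):
                work[ri, ci] = v
                fill_cell(ci + 1, rem - v)

        fill_cell(0, int(rows[ri]))

    fill_row(0, cols.copy())
    return out


def exact_test(table, budget_n: int = 200) -> ExactTestResult:
    """Exact p together with chi-square effect size on one table."""
    chi = chi_square_cramers_v(table)
    p = freeman_halton_exact(table, budget_n=budget_n)
    return ExactTestResult(p, chi.chi2, chi.cramers_v, chi.effective_dims)


def icc_absolute_agreement(ratings) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_subjects x k_raters) matrix with no missing
    cells.  ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Zero between-subject variance yields ICC 0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ParameterError("ratings must be n_subjects x k_raters, both >= 2")
    if not np.isfinite(x).all():
        raise InputError("ratings contain missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ssr = k * ((subj_means - grand) ** 2).sum()
    ssc = n * ((rater_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr <= 1e-300 or denom <= 0:
        warnings.warn("zero between-subject variance; ICC reported as 0")
        icc = 0.0
    else:
        icc = float((msr - mse) / denom)
    return ICCResult(
        icc=icc,
        model="two-way random, absolute agreement, single rater (ICC(A,1))",
        var_subjects=max(0.0, (msr - mse) / k),
        var_raters=max(0.0, (msc - mse) / n),
        var_error=float(mse),
    )
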