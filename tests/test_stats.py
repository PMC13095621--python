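import math
from fractions import Fraction
from itertools import product
from math import factorial

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from endplate.errors import EnumerationBudgetError, InputError, \
    ParameterError, UndefinedEffectError
from endplate.reference import contingency_for_segment, \
    depth_summaries_for_segment
from endplate.stats import GroupSummary, chi_square_cramers_v, \
    enumerate_margin_tables, freeman_halton_exact, icc_absolute_agreement, \
    pooled_t_test

# ---------------------------------------------------------------- t-test

# Printed reference rows (segment, plane, t, d, ci_low, ci_high).  The
# printed group means/SDs are rounded to 2 dp; rounding each mean by up
# to 0.005 perturbs the recomputed t by up to 0.01/SE and d by up to
# 0.01/sp, so each quantity is compared at half a printed ulp plus that
# propagated input-rounding bound.
REFERENCE_T_ROWS = [
    ("L4_inf", "sagittal", -1.61, -0.57, -0.66, 0.08),
    ("S1_sup", "sagittal", 1.03, 0.36, -0.18, 0.56),
    ("L4_inf", "coronal", -0.72, -0.25, -1.03, 0.49),
    ("L4_sup", "sagittal", -0.15, -0.05, -0.46, 0.40),
    ("L5_inf", "coronal", -0.26, -0.09, -0.66, 0.51),
]


@pytest.mark.parametrize("segment,plane,t,d,lo,hi", REFERENCE_T_ROWS)
def test_pooled_t_reproduces_reference_rows(segment, plane, t, d, lo, hi):
    g1, g2 = depth_summaries_for_segment(plane, segment)
    res = pooled_t_test(g1, g2)
    df = g1.n + g2.n - 2
    sp = math.sqrt(((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df)
    se = sp * math.sqrt(1 / g1.n + 1 / g2.n)
    assert res.t == pytest.approx(t, abs=0.005 + 0.01 / se)
    assert res.cohens_d == pytest.approx(d, abs=0.005 + 0.01 / sp)
    assert res.ci_low == pytest.approx(lo, abs=0.02)
    assert res.ci_high == pytest.approx(hi, abs=0.02)
    assert res.df == df


def test_pooled_not_welch_matches_reference():
    """The reference table's t follows the pooled formula; Welch does not."""
    g1, g2 = depth_summaries_for_segment("sagittal", "L4_inf")
    pooled = pooled_t_test(g1, g2).t
    welch = sps.ttest_ind_from_stats(g1.mean, g1.sd, g1.n,
                                     g2.mean, g2.sd, g2.n,
                                     equal_var=False).statistic
    assert abs(pooled - (-1.61)) < abs(welch - (-1.61))


def test_identical_groups():
    g = GroupSummary(10, 1.5, 0.4)
    res = pooled_t_test(g, g)
    assert res.t == 0.0 and res.cohens_d == 0.0
    assert res.ci_low == pytest.approx(-res.ci_high)


def test_summary_matches_raw_sample_oracle():
    """pooled_t_test on summaries == scipy's equal-variance t on raw data."""
    rng = np.random.default_rng(7)
    a, b = rng.normal(1.7, 0.5, 19), rng.normal(2.0, 0.45, 14)
    res = pooled_t_test(GroupSummary.from_data(a), GroupSummary.from_data(b))
    ref = sps.ttest_ind(a, b, equal_var=True)
    assert res.t == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


@given(n1=st.integers(2, 40), n2=st.integers(2, 40),
       m1=st.floats(-5, 5), m2=st.floats(-5, 5),
       s1=st.floats(0.1, 3), s2=st.floats(0.1, 3))
def test_t_antisymmetry(n1, n2, m1, m2, s1, s2):
    """Swapping the groups negates t, d and mirrors the CI."""
    a, b = GroupSummary(n1, m1, s1), GroupSummary(n2, m2, s2)
    r1, r2 = pooled_t_test(a, b), pooled_t_test(b, a)
    assert r1.t == pytest.approx(-r2.t, rel=1e-12, abs=1e-12)
    assert r1.cohens_d == pytest.approx(-r2.cohens_d, rel=1e-12, abs=1e-12)
    assert r1.ci_low == pytest.approx(-r2.ci_high, rel=1e-12, abs=1e-12)


def test_degenerate_groups():
    with pytest.raises(ParameterError):
        GroupSummary(1, 0.0, 0.0)
    with pytest.raises(ParameterError):
        pooled_t_test(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))


# ------------------------------------------------- chi-square / Cramér's V

REFERENCE_V_ROWS = [
    ("sagittal", "L4_sup", 0.41, (2, 4)),
    ("sagittal", "L5_inf", 0.10, (2, 4)),
    ("coronal", "L5_sup", 0.34, (2, 3)),   # one all-zero column dropped
    ("coronal", "S1_sup", 0.19, (2, 2)),   # two all-zero columns dropped
]


@pytest.mark.parametrize("plane,segment,v,dims", REFERENCE_V_ROWS)
def test_cramers_v_reproduces_reference(plane, segment, v, dims):
    res = chi_square_cramers_v(contingency_for_segment(plane, segment))
    assert res.cramers_v == pytest.approx(v, abs=0.005)
    assert res.effective_dims == dims


def test_perfect_association():
    res = chi_square_cramers_v([[5, 0], [0, 5]])
    assert res.cramers_v == pytest.approx(1.0)


def test_v_permutation_invariance():
    rng = np.random.default_rng(1)
    tab = rng.integers(0, 12, size=(3, 4))
    tab[0, 0] += 1  # guarantee a positive total
    base = chi_square_cramers_v(tab).cramers_v
    perm = chi_square_cramers_v(tab[::-1][:, [2, 0, 3, 1]]).cramers_v
    assert perm == pytest.approx(base, rel=1e-12)
    assert 0.0 <= base <= 1.0


def test_v_undefined_on_collapsed_table():
    with pytest.raises(UndefinedEffectError):
        chi_square_cramers_v([[3, 0], [4, 0]])
    with pytest.raises(InputError):
        chi_square_cramers_v([[0, 0], [0, 0]])


# ---------------------------------------------------- Freeman–Halton exact


def exact_p_fraction_oracle(table) -> float:
    """Independent brute-force oracle: enumerate first-row candidates with
    itertools.product and exact Fraction arithmetic."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())

    def prob(cells) -> Fraction:
        num = Fraction(1)
        for x in rows:
            num *= factorial(int(x))
        for x in cols:
            num *= factorial(int(x))
        den = Fraction(factorial(n))
        for x in cells:
            den *= factorial(int(x))
        return num / den

    assert t.shape[0] == 2, "oracle written for 2-row tables"
    p_obs = prob(t.ravel())
    total = Fraction(0)
    p_val = Fraction(0)
    ranges = [range(int(c) + 1) for c in cols]
    for first in product(*ranges):
        if sum(first) != rows[0]:
            continue
        second = cols - np.asarray(first)
        if (second < 0).any():
            continue
        p = prob(list(first) + second.tolist())
        total += p
        if p <= p_obs:
            p_val += p
    assert abs(float(total) - 1.0) < 1e-12
    return float(p_val)


def test_exact_reference_table():
    p = freeman_halton_exact(contingency_for_segment("sagittal", "L4_sup"))
    assert p == pytest.approx(0.14, abs=0.005)


def test_exact_two_by_two_trivial():
    assert freeman_halton_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)


@given(st.integers(0, 10**6))
def test_exact_matches_fisher_on_2x2(seed):
    rng = np.random.default_rng(seed)
    tab = rng.integers(0, 8, size=(2, 2))
    tab[0, 0] += 1
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        return
    ours = freeman_halton_exact(tab)
    ref = sps.fisher_exact(tab).pvalue
    assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


@given(st.integers(0, 10**6))
def test_exact_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    tab = rng.multinomial(20, np.full(6, 1 / 6)).reshape(2, 3)
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        return
    assert freeman_halton_exact(tab) == pytest.approx(
        exact_p_fraction_oracle(tab), rel=1e-12, abs=1e-12)


def test_exact_invariant_to_zero_margins():
    tab = np.array([[4, 5, 2, 8], [5, 2, 5, 2]])
    padded = np.zeros((3, 5), dtype=int)
    padded[:2, :4] = tab
    assert freeman_halton_exact(padded) == pytest.approx(
        freeman_halton_exact(tab), rel=1e-12)


def test_enumeration_probabilities_sum_to_one():
    tab = contingency_for_segment("sagittal", "L4_sup")
    probs = [p for _, p in enumerate_margin_tables(tab)]
    assert math.fsum(probs) == pytest.approx(1.0, abs=1e-10)


def test_enumeration_budget():
    big = np.full((2, 4), 40)
    with pytest.raises(EnumerationBudgetError):
        freeman_halton_exact(big, budget_n=200)


# ----------------------------------------------------------------- ICC


def test_icc_identical_raters():
    x = np.arange(10, dtype=float).reshape(-1, 1)
    res = icc_absolute_agreement(np.hstack([x, x]))
    assert res.icc == pytest.approx(1.0)


def test_icc_recovers_variance_ratio():
    from endplate.validation import simulate_icc
    sim = simulate_icc(n_subjects=50, seed=3)
    assert sim.abs_error <= 0.1


def test_icc_zero_between_subject_variance():
    x = np.ones((6, 2))
    x[:, 1] += 0.5
    with pytest.warns(UserWarning):
        res = icc_absolute_agreement(x)
    assert res.icc == 0.0


def test_icc_matches_pingouin():
    """Cross-check ICC(A,1) against pingouin's ICC2 (two-way random,
    absolute agreement, single rater)."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(12)
    n, k = 20, 3
    x = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.2, (1, k)) \
        + rng.normal(0, 0.4, (n, k))
    ours = icc_absolute_agreement(x).icc
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
    ref_icc = float(ref.set_index("Type").loc["ICC(A,1)", "ICC"])
    assert ours == pytest.approx(ref_icc, abs=1e-9)


def test_icc_input_validation():
    with pytest.raises(ParameterError):
        icc_absolute_agreement(np.ones((1, 2)))
    with pytest.raises(InputError):
        icc_absolute_agreement([[1.0, np.nan], [2.0, 2.0], [3.0, 3.1]])
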