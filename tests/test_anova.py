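"""t/F reconstruction from summaries, rounding bounds, and p/bounds verdicts."""

import math
from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from statforensics import (
    FactorialGrid,
    GroupSummary,
    RecomputedTest,
    StatBounds,
    bounds_verdict,
    generate,
    oneway_f,
    p_agreement,
    pooled_t,
    raw_f_oracle,
    stat_bounds,
    summarize,
    twoway_f,
)
from statforensics.errors import CapacityError, InvalidInputError


def grp(label, n, mean, sd):
    return GroupSummary.make(label, n, mean, sd)


def balanced_grid(cell_params):
    """cell_params: 2x2 nested list of (n, mean, sd)."""
    cells = tuple(
        tuple(grp(f"{i}{j}", *cell_params[i][j]) for j in range(2)) for i in range(2)
    )
    return FactorialGrid(("a1", "a2"), ("b1", "b2"), cells)


# ---------------------------------------------------------------------------
# one-way F and pooled t


def test_oneway_f_closed_form_example():
    rt = oneway_f([grp("a", 10, "2.00", "1.00"), grp("b", 10, "3.00", "1.00")])
    assert rt.family == "F"
    assert (rt.df1, rt.df2) == (1, 18)
    assert rt.statistic == pytest.approx(5.0, abs=1e-12)


def test_oneway_f_is_zero_for_identical_means():
    groups = [grp(str(i), 8, "4.20", "1.30") for i in range(4)]
    rt = oneway_f(groups)
    assert rt.statistic == 0.0
    assert rt.p == 1.0


def test_oneway_degenerate_zero_variance_cases():
    same = oneway_f([grp("a", 5, "2.00", "0.00"), grp("b", 5, "2.00", "0.00")])
    assert same.statistic == 0.0 and same.p == 1.0 and not same.overflow
    diff = oneway_f([grp("a", 5, "2.00", "0.00"), grp("b", 5, "3.00", "0.00")])
    assert math.isinf(diff.statistic) and diff.p == 0.0 and diff.overflow


def test_pooled_t_is_square_root_of_two_group_f():
    t = pooled_t(grp("a", 10, "2.00", "1.00"), grp("b", 10, "3.00", "1.00"))
    assert abs(t.statistic) == pytest.approx(math.sqrt(5), abs=1e-12)
    assert t.df2 == 18
    t0 = pooled_t(grp("a", 6, "2.50", "1.10"), grp("b", 6, "2.50", "1.10"))
    assert t0.statistic == 0.0 and t0.p == 1.0


@given(
    st.integers(2, 40), st.integers(2, 40),
    st.integers(0, 600), st.integers(0, 600),
    st.integers(1, 300), st.integers(1, 300),
)
@settings(max_examples=200, deadline=None)
def test_t_squared_equals_f_identity(n1, n2, m1, m2, s1, s2):
    g1 = grp("a", n1, Decimal(m1).scaleb(-2), Decimal(s1).scaleb(-2))
    g2 = grp("b", n2, Decimal(m2).scaleb(-2), Decimal(s2).scaleb(-2))
    t = pooled_t(g1, g2)
    f = oneway_f([g1, g2])
    assert t.statistic ** 2 == pytest.approx(f.statistic, rel=1e-10, abs=1e-10)
    assert (t.df2, f.df2) == (n1 + n2 - 2, n1 + n2 - 2)


def test_oneway_matches_raw_data_and_scipy():
    for seed in range(50):
        ds = generate(seed, 3, 15, (1, 9), effects=[0.0, 0.4, 0.8])
        exact = summarize(ds, Decimal("1E-12"))
        rt = oneway_f(exact)
        raw = raw_f_oracle(ds)
        scipy_f = stats.f_oneway(*[np.array(g.values) for g in ds.groups]).statistic
        assert rt.statistic == pytest.approx(raw.statistic, rel=1e-9)
        assert raw.statistic == pytest.approx(scipy_f, rel=1e-9)


def test_scale_and_shift_equivariance_of_f():
    base = [grp("a", 12, "2.10", "0.80"), grp("b", 9, "3.40", "1.20"), grp("c", 7, "2.90", "0.60")]
    shifted = [grp(g.label, g.n, g.mean.value + 5, g.sd.value) for g in base]
    scaled = [grp(g.label, g.n, g.mean.value * 2, g.sd.value * 2) for g in base]
    f0 = oneway_f(base).statistic
    assert oneway_f(shifted).statistic == pytest.approx(f0, rel=1e-12)
    assert oneway_f(scaled).statistic == pytest.approx(f0, rel=1e-12)


# ---------------------------------------------------------------------------
# two-way F


def test_twoway_null_grid_gives_zero_everywhere():
    grid = balanced_grid([[(10, "3.00", "1.00")] * 2] * 2)
    res = twoway_f(grid)
    for rt in (res.main_a, res.main_b, res.interaction):
        assert rt.statistic == 0.0
        assert rt.df2 == 36


def test_twoway_pure_main_effect_leaves_other_effects_zero():
    grid = balanced_grid([
        [(10, "2.00", "1.00"), (10, "2.00", "1.00")],
        [(10, "3.00", "1.00"), (10, "3.00", "1.00")],
    ])
    res = twoway_f(grid)
    assert res.main_a.statistic > 0
    assert res.main_b.statistic == 0.0
    assert res.interaction.statistic == 0.0
    assert (res.main_a.df1, res.main_a.df2) == (1, 36)


def test_twoway_balanced_matches_statsmodels():
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(7)
    rows, data = [], []
    for a in ("a1", "a2"):
        row = []
        for b in ("b1", "b2"):
            vals = rng.integers(1, 8, size=12)
            data.extend({"A": a, "B": b, "y": int(v)} for v in vals)
            mean = Decimal(repr(round(float(vals.mean()), 9))).quantize(Decimal("1E-9"))
            sd = Decimal(repr(round(float(vals.std(ddof=1)), 9))).quantize(Decimal("1E-9"))
            row.append(GroupSummary.make(f"{a}{b}", 12, mean, sd, "1E-9"))
        rows.append(tuple(row))
    grid = FactorialGrid(("a1", "a2"), ("b1", "b2"), tuple(rows))
    res = twoway_f(grid)
    tab = sm.stats.anova_lm(ols("y ~ C(A)*C(B)", pd.DataFrame(data)).fit(), typ=2)
    expected = list(tab["F"][:3])
    assert res.main_a.statistic == pytest.approx(expected[0], rel=1e-6)
    assert res.main_b.statistic == pytest.approx(expected[1], rel=1e-6)
    assert res.interaction.statistic == pytest.approx(expected[2], rel=1e-6)


def test_twoway_missing_cell_is_rejected():
    cells = ((grp("a", 5, "1.00", "1.00"),),)
    with pytest.raises(InvalidInputError):
        FactorialGrid(("a1", "a2"), ("b1",), cells)


# ---------------------------------------------------------------------------
# rounding-precision bounds


def test_zero_perturbation_collapses_bounds_to_the_exact_statistic():
    groups = [grp("a", 10, "2.00", "1.00"), grp("b", 10, "3.00", "1.00")]
    b = stat_bounds(groups, "F", perturbation="0")
    f = oneway_f(groups).statistic
    assert b.lower == b.upper == pytest.approx(f, abs=1e-12)


def test_bounds_extremes_attained_at_extreme_mean_separation():
    groups = [grp("a", 10, "2.00", "1.00"), grp("b", 10, "3.00", "1.00")]
    b = stat_bounds(groups, "F")

    def f(m1, m2, s):
        grand = (m1 + m2) / 2
        ssb = 10 * (m1 - grand) ** 2 + 10 * (m2 - grand) ** 2
        return ssb / (s * s)

    assert b.upper == pytest.approx(f(1.995, 3.005, 0.995), rel=1e-12)
    assert b.lower == pytest.approx(f(2.005, 2.995, 1.005), rel=1e-12)


def test_bounds_contain_raw_statistic_for_rounded_summaries():
    for seed in range(100):
        ds = generate(seed, 2, 25, (1, 9), effects=[0.0, 0.5])
        b = stat_bounds(summarize(ds), "F")
        assert b.lower <= raw_f_oracle(ds).statistic <= b.upper


def test_bounds_sd_floor_keeps_sds_nonnegative():
    groups = [grp("a", 5, "1.00", "0.00"), grp("b", 5, "2.00", "0.00")]
    b = stat_bounds(groups, "F")
    assert math.isinf(b.upper)  # zero SDs with unequal means: unbounded above
    assert b.lower > 0


def test_bounds_capacity_guard_refuses_large_enumerations():
    groups = [grp(str(i), 5, "2.00", "1.00") for i in range(21)]
    with pytest.raises(CapacityError):
        stat_bounds(groups, "F")


def test_grid_bounds_contain_the_exact_effect_statistic():
    grid = balanced_grid([
        [(10, "2.10", "1.00"), (10, "2.70", "0.90")],
        [(10, "3.00", "1.10"), (10, "2.40", "1.20")],
    ])
    res = twoway_f(grid)
    for selector, rt in (("A", res.main_a), ("B", res.main_b), ("interaction", res.interaction)):
        b = stat_bounds(grid, selector)
        assert b.lower <= rt.statistic <= b.upper


# ---------------------------------------------------------------------------
# verdicts


def f_test(stat, df1, df2):
    return RecomputedTest("F", stat, df1, df2, p=float(stats.f.sf(stat, df1, df2)))


@pytest.mark.parametrize(
    "rt,reported,expected",
    [
        (f_test(4.24, 1, 122), "0.04", "consistent"),      # true p ~ 0.0416
        (f_test(4.24, 1, 122), "0.05", "inconsistent"),
        (f_test(90.93, 2, 60), "< 0.01", "consistent"),
        (f_test(1.34, 1, 120), "> 0.05", "consistent"),
        (RecomputedTest("t", 0.0, 1, 18, p=1.0), "1.00", "consistent"),
    ],
)
def test_p_agreement_verdicts(rt, reported, expected):
    assert p_agreement(rt, reported).severity == expected


def test_p_agreement_rejects_impossible_p():
    with pytest.raises(InvalidInputError):
        p_agreement(f_test(1.0, 1, 10), "1.50")


@pytest.mark.parametrize(
    "reported,lower,upper,expected",
    [
        ("0.42", 0.39, 0.40, "inconsistent"),
        ("14.04", 13.41, 14.04, "consistent"),   # boundary touch counts
        ("13.80", 13.41, 14.04, "consistent"),
        ("15.42", 13.41, 14.04, "inconsistent"),
    ],
)
def test_bounds_verdicts(reported, lower, upper, expected):
    assert bounds_verdict(reported, StatBounds(lower, upper)).severity == expected
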