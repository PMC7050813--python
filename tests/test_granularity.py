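"""GRIM and GRIMMER verdicts against worked examples and brute-force oracles."""

from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from statforensics import (
    ReportedMean,
    ReportedSD,
    RoundedValue,
    grim_check,
    grim_reachable,
    grimmer_check,
)
from statforensics.errors import InvalidInputError
from statforensics.rounding import achievable_roundings


def rmean(text, n, **kw):
    return ReportedMean(RoundedValue.from_text(text), n, **kw)


def rsd(sd_text, n, mean_text=None, item_range=None):
    mean = rmean(mean_text, n) if mean_text is not None else None
    return ReportedSD(RoundedValue.from_text(sd_text), n, mean=mean, item_range=item_range)


# ---------------------------------------------------------------------------
# GRIM


@pytest.mark.parametrize(
    "mean,n,kw,expected",
    [
        ("6.62", 62, {}, False),           # impossible at n=62
        ("2.25", 10, {}, False),           # n=10 means need a trailing zero
        ("4.26", 58, {}, True),
        ("4.27", 58, {}, False),
        ("4.28", 58, {}, True),
        ("3.50", 10, {}, True),            # S = 35
        ("57.4", 62, {"multiplier": 100}, False),  # percentage granularity
        ("47.9", 60, {"multiplier": 100}, False),
    ],
)
def test_grim_worked_examples(mean, n, kw, expected):
    assert grim_check(rmean(mean, n, **kw)).consistent is expected


def test_grim_consistent_verdicts_carry_integer_witnesses():
    v = grim_check(rmean("3.50", 10))
    assert v.consistent
    assert [w[0] for w in v.witnesses] == [35]


def test_grim_inconsistent_verdicts_bracket_the_reported_value():
    v = grim_check(rmean("6.62", 62))
    assert not v.consistent
    assert v.nearest_below == Decimal("6.61")
    assert v.nearest_above == Decimal("6.63")
    assert v.nearest_below < Decimal("6.62") < v.nearest_above


def test_grim_multi_item_scale_refines_granularity():
    # a 3-item composite at n=10 averages 30 integers: 2.23 needs S/30 in range
    assert not grim_check(rmean("2.25", 10)).consistent
    assert grim_check(rmean("2.23", 10, items=3)).consistent


@pytest.mark.parametrize("bad_n", [0, -5])
def test_grim_rejects_nonpositive_n(bad_n):
    with pytest.raises(InvalidInputError):
        rmean("2.00", bad_n)


def test_grim_reachable_examples():
    assert grim_reachable(10, (Decimal("2.20"), Decimal("2.30"))) == [
        Decimal("2.20"), Decimal("2.30")
    ]
    assert grim_reachable(1, (Decimal("1.00"), Decimal("2.00"))) == [
        Decimal("1.00"), Decimal("2.00")
    ]
    assert grim_reachable(5, (Decimal("2.0"), Decimal("1.0"))) == []  # inverted window


def test_grim_reachable_n58_matches_sum_enumeration():
    # oracle: every value any integer sum 246..249 can print to, within window
    expected = set()
    for s in range(246, 250):
        for g in achievable_roundings(Fraction(s, 58), Decimal("0.01")):
            if Decimal("4.25") <= g <= Decimal("4.29"):
                expected.add(g)
    assert expected == {Decimal("4.26"), Decimal("4.28"), Decimal("4.29")}
    assert grim_reachable(58, (Decimal("4.25"), Decimal("4.29"))) == sorted(expected)


def test_grim_agrees_with_sum_enumeration_up_to_n_200():
    """Verdicts equal brute-force achievability for every two-decimal mean in [1, 9]."""
    p = Decimal("0.01")
    for n in range(1, 201):
        achievable = set()
        for s in range(n - 1, 9 * n + 2):
            achievable.update(achievable_roundings(Fraction(s, n), p))
        for k in range(100, 901):
            mean = Decimal(k).scaleb(-2)
            verdict = grim_check(ReportedMean(RoundedValue(mean, p), n), neighbours=False)
            assert verdict.consistent == (mean in achievable), (n, mean)


@given(st.integers(1, 99), st.integers(100, 900))
@settings(max_examples=200, deadline=None)
def test_grim_consistency_coarsens_monotonically(n, tenth_k):
    """A mean consistent at two decimals stays consistent reported at one decimal."""
    mean_fine = Decimal(tenth_k).scaleb(-2)
    if mean_fine != mean_fine.quantize(Decimal("0.1")):
        return  # value must live on the coarser grid to be reportable there
    fine = grim_check(ReportedMean(RoundedValue(mean_fine, Decimal("0.01")), n), neighbours=False)
    coarse = grim_check(
        ReportedMean(RoundedValue(mean_fine.quantize(Decimal("0.1")), Decimal("0.1")), n),
        neighbours=False,
    )
    if fine.consistent:
        assert coarse.consistent


@given(st.lists(st.integers(1, 7), min_size=2, max_size=40))
@settings(max_examples=200, deadline=None)
def test_grim_never_flags_truly_rounded_means(values):
    """Soundness: the rounded mean of real integer data is always consistent."""
    n = len(values)
    from statforensics.rounding import round_to_precision

    mean = round_to_precision(Fraction(sum(values), n), Decimal("0.01"))
    v = grim_check(ReportedMean(RoundedValue(mean, Decimal("0.01")), n), neighbours=False)
    assert v.consistent


# ---------------------------------------------------------------------------
# GRIMMER


@pytest.mark.parametrize(
    "sd,n,mean,item_range,expected",
    [
        ("0.40", 10, "1.18", None, False),   # mean itself fails GRIM
        ("0.00", 10, "2.00", None, True),    # ten identical responses
        ("1.58", 5, "3.00", (1, 5), True),   # witness data 1,2,3,4,5
        ("0.71", 2, "1.50", (1, 2), True),   # sd of {1,2} = sqrt(0.5)
        ("0.70", 2, "1.50", (1, 2), False),
    ],
)
def test_grimmer_worked_examples(sd, n, mean, item_range, expected):
    assert grimmer_check(rsd(sd, n, mean, item_range)).consistent is expected


def test_grimmer_witness_reproduces_the_reported_pair():
    v = grimmer_check(rsd("1.58", 5, "3.00", (1, 5)))
    assert v.consistent
    s, q = v.witnesses[0]
    assert (s, q) == (15, 55)  # e.g. the multiset {1,2,3,4,5}


def test_grimmer_requires_n_at_least_two():
    with pytest.raises(InvalidInputError):
        ReportedSD(RoundedValue.from_text("1.00"), 1)


def test_grimmer_mean_incompatible_with_item_range_is_a_verdict_not_an_error():
    v = grimmer_check(rsd("1.00", 10, "8.50", (1, 7)))
    assert not v.consistent
    assert "item range" in v.detail


def test_grimmer_without_mean_uses_documented_search_window():
    # sd 0.50 at n=4: e.g. values {1,1,2,2} give sd sqrt(1/3)=0.577; {2,2,2,3} -> 0.5
    assert grimmer_check(ReportedSD(RoundedValue.from_text("0.50"), 4)).consistent
    # sd below any nonzero granularity step at n=4 is impossible
    assert not grimmer_check(ReportedSD(RoundedValue.from_text("0.20"), 4)).consistent


def test_population_sd_option_changes_the_verdict():
    # {1,2} has sample sd 0.71 but population sd 0.50
    sample = grimmer_check(rsd("0.50", 2, "1.50", (1, 2)))
    population = grimmer_check(rsd("0.50", 2, "1.50", (1, 2)), population_sd=True)
    assert not sample.consistent
    assert population.consistent


@given(st.integers(2, 40), st.integers(100, 900))
@settings(max_examples=100, deadline=None)
def test_grim_inconsistent_mean_forces_grimmer_inconsistent(n, k):
    mean = Decimal(k).scaleb(-2)
    rm = ReportedMean(RoundedValue(mean, Decimal("0.01")), n)
    if grim_check(rm, neighbours=False).consistent:
        return
    rs = ReportedSD(RoundedValue.from_text("1.00"), n, mean=rm)
    assert not grimmer_check(rs, neighbours=False).consistent
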