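"""Granularity tests for reported means and standard deviations.

Statistics of integer-valued data (Likert items, counts, percentages of a
sample) are *granular*: at sample size ``n`` a mean can only be a multiple of
``1/n``, which for ``n < 100`` is coarser than the two decimal places at which
means are usually printed.  A printed mean that no integer total can produce is
therefore arithmetically impossible, whatever the underlying data were.

* :func:`grim_check` decides whether a reported mean (or percentage) is
  achievable at the stated sample size — the GRIM test.
* :func:`grimmer_check` does the same for a sample standard deviation, by
  searching for an integer sum ``S`` and sum of squares ``Q`` that reproduce
  both the printed mean and the printed SD — the GRIMMER test.

Both use the inclusive rounding intervals of :mod:`statforensics.rounding`,
so a value exactly on a rounding boundary is accepted; verdicts are strictly
conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from functools import lru_cache

from .errors import CapacityError, InvalidInputError
from .rounding import RoundedValue, achievable_roundings, as_decimal

__all__ = [
    "ReportedMean",
    "ReportedSD",
    "GranularityVerdict",
    "grim_check",
    "grim_reachable",
    "grimmer_check",
]

# Largest value-domain width the sum-of-squares feasibility search will accept.
_MAX_DOMAIN = 4000


@dataclass(frozen=True)
class ReportedMean:
    """A published mean with its sample size.

    ``multiplier`` is 1 for raw means and 100 for percentages; ``items`` is the
    number of averaged scale items (the mean of a 3-item composite of integer
    responses has granularity 1/(3n)).
    """

    mean: RoundedValue
    n: int
    multiplier: int | Decimal = 1
    items: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError(f"sample size must be positive, got {self.n}")
        if self.items < 1:
            raise InvalidInputError(f"items must be positive, got {self.items}")
        if Fraction(as_decimal(self.multiplier)) <= 0:
            raise InvalidInputError("multiplier must be positive")

    @property
    def denominator(self) -> int:
        return self.n * self.items


@dataclass(frozen=True)
class ReportedSD:
    """A published sample SD (denominator n-1), optionally with its mean.

    ``item_range`` bounds the underlying integer responses, e.g. ``(1, 7)``
    for a 7-point scale; when absent the response scale is treated as unknown.
    """

    sd: RoundedValue
    n: int
    mean: ReportedMean | None = None
    item_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"SD requires n >= 2, got {self.n}")
        if self.sd.value < 0:
            raise InvalidInputError(f"SD must be nonnegative, got {self.sd.value}")
        if self.item_range is not None:
            lo, hi = self.item_range
            if hi <= lo:
                raise InvalidInputError(f"item_range must satisfy hi > lo, got {self.item_range}")


@dataclass
class GranularityVerdict:
    """Outcome of a granularity check.

    ``witnesses`` holds (sum, sum_of_squares) pairs proving consistency (the
    sum-of-squares entry is None for a mean-only check); ``nearest_below`` and
    ``nearest_above`` are the closest achievable printed values on either side
    of the reported one.
    """

    consistent: bool
    nearest_below: Decimal | None = None
    nearest_above: Decimal | None = None
    witnesses: list[tuple[int, int | None]] = field(default_factory=list)
    detail: str = ""


# ---------------------------------------------------------------------------
# GRIM


def _sum_range(rm: ReportedMean) -> tuple[int, int]:
    """Integer totals S whose exact mean lies in the reported interval."""
    lo, hi = rm.mean.interval()
    mult = Fraction(as_decimal(rm.multiplier))
    denom = rm.denominator
    s_lo = math.ceil(lo * denom / mult)
    s_hi = math.floor(hi * denom / mult)
    return s_lo, s_hi


def grim_check(rm: ReportedMean, neighbours: bool = True) -> GranularityVerdict:
    """GRIM test: is the reported mean achievable from any integer total?

    Consistent iff some integer total ``S`` gives ``S/(n*items) * multiplier``
    inside the inclusive rounding interval of the printed mean.
    ``neighbours=False`` skips locating the nearest achievable values.
    """
    s_lo, s_hi = _sum_range(rm)
    consistent = s_lo <= s_hi
    witnesses = [(s, None) for s in range(s_lo, s_hi + 1)] if consistent else []
    below, above = _grim_neighbours(rm) if neighbours else (None, None)
    return GranularityVerdict(
        consistent=consistent,
        nearest_below=below,
        nearest_above=above,
        witnesses=witnesses,
        detail="" if consistent else (
            f"no integer total in [{s_lo}, {s_hi}] reproduces "
            f"{rm.mean.value} at n={rm.n}"
        ),
    )


def _grim_neighbours(rm: ReportedMean) -> tuple[Decimal | None, Decimal | None]:
    """Closest achievable printed values strictly below / above the reported one."""
    p = rm.mean.precision
    mult = Fraction(as_decimal(rm.multiplier))
    # granularity step in printed units; achievable values are at most this far apart
    step = mult / rm.denominator
    max_steps = math.ceil(step / Fraction(p)) + 2
    below = above = None
    for k in range(1, max_steps + 1):
        cand = rm.mean.value - k * p
        if below is None and _grim_value_ok(cand, rm):
            below = cand
        cand = rm.mean.value + k * p
        if above is None and _grim_value_ok(cand, rm):
            above = cand
        if below is not None and above is not None:
            break
    return below, above


def _grim_value_ok(value: Decimal, rm: ReportedMean) -> bool:
    try:
        cand = ReportedMean(
            RoundedValue(value, rm.mean.precision), rm.n, rm.multiplier, rm.items
        )
    except InvalidInputError:
        return False
    s_lo, s_hi = _sum_range(cand)
    return s_lo <= s_hi


def grim_reachable(
    n: int,
    window: tuple[Decimal | str, Decimal | str],
    items: int = 1,
    multiplier: int | Decimal = 1,
    precision: Decimal | str = Decimal("0.01"),
) -> list[Decimal]:
    """All printed values achievable in ``window`` at sample size ``n``.

    Returns the sorted set { rounding of S/(n*items)*multiplier : S integer }
    intersected with the inclusive window; exact midpoints contribute both
    neighbours.  An empty or inverted window yields an empty list.
    """
    if n < 1 or items < 1:
        raise InvalidInputError("n and items must be positive")
    precision = as_decimal(precision)
    if precision <= 0:
        raise InvalidInputError("precision must be > 0")
    w_lo, w_hi = (Fraction(as_decimal(w)) for w in window)
    if w_hi < w_lo:
        return []
    mult = Fraction(as_decimal(multiplier))
    denom = n * items
    half = Fraction(precision) / 2
    s_lo = math.ceil((w_lo - half) * denom / mult)
    s_hi = math.floor((w_hi + half) * denom / mult)
    out: set[Decimal] = set()
    for s in range(s_lo, s_hi + 1):
        v = Fraction(s) * mult / denom
        for g in achievable_roundings(v, precision):
            if w_lo <= Fraction(g) <= w_hi:
                out.add(g)
    return sorted(out)


# ---------------------------------------------------------------------------
# GRIMMER


def grimmer_check(
    rs: ReportedSD, population_sd: bool = False, neighbours: bool = True
) -> GranularityVerdict:
    """GRIMMER test: is the reported SD achievable from integer data?

    Searches for an integer sum ``S`` and sum of squares ``Q`` of ``n``
    integers such that (a) ``S/n`` lies in the reported mean's interval (when
    a mean is given), (b) the implied SD lies in the reported SD's interval,
    and (c) a multiset of ``n`` integers with sum ``S`` and sum of squares
    ``Q`` actually exists (within ``item_range`` when given).  Existence is
    decided exactly by a pruned feasibility search, so verdicts agree with
    exhaustive enumeration.

    With ``population_sd=True`` the SD is interpreted with denominator ``n``
    instead of the default sample convention ``n - 1``.  ``neighbours=False``
    skips the (slower) search for the nearest achievable SD values on an
    inconsistent verdict.
    """
    n = rs.n
    if rs.mean is not None and (rs.mean.items != 1 or as_decimal(rs.mean.multiplier) != 1):
        raise InvalidInputError(
            "grimmer_check supports raw means only (items=1, multiplier=1)"
        )

    sd_lo, sd_hi = rs.sd.interval()
    sd_lo = max(sd_lo, Fraction(0))
    ddof = n if population_sd else n - 1
    # target: (n*Q - S^2)/n must lie in [ddof*sd_lo^2, ddof*sd_hi^2]
    var_lo = sd_lo * sd_lo * ddof
    var_hi = sd_hi * sd_hi * ddof

    s_values, note = _grimmer_sum_candidates(rs)
    if not s_values:
        below, above = _grimmer_neighbours(rs, population_sd) if neighbours else (None, None)
        return GranularityVerdict(
            consistent=False, nearest_below=below, nearest_above=above,
            detail=note or "no feasible integer sum for the reported mean",
        )

    witnesses: list[tuple[int, int | None]] = []
    for s in s_values:
        q_lo = math.ceil(Fraction(s * s, n) + var_lo)
        q_hi = math.floor(Fraction(s * s, n) + var_hi)
        for q in range(q_lo, q_hi + 1):
            if (q - s) % 2 != 0:  # sum and sum of squares of integers share parity
                continue
            if _feasible_multiset(n, s, q, rs.item_range) is not None:
                witnesses.append((s, q))
                break
        if witnesses:
            break

    if witnesses:
        return GranularityVerdict(consistent=True, witnesses=witnesses)
    below, above = _grimmer_neighbours(rs, population_sd) if neighbours else (None, None)
    return GranularityVerdict(
        consistent=False, nearest_below=below, nearest_above=above,
        detail=note or (
            f"no integer (sum, sum-of-squares) pair reproduces SD {rs.sd.value} at n={n}"
        ),
    )


def _grimmer_sum_candidates(rs: ReportedSD) -> tuple[range, str]:
    """Integer sums compatible with the mean (or a documented default window)."""
    n = rs.n
    note = ""
    if rs.mean is not None:
        s_lo, s_hi = _sum_range(rs.mean)
        if rs.item_range is not None:
            lo, hi = rs.item_range
            clipped_lo, clipped_hi = max(s_lo, n * lo), min(s_hi, n * hi)
            if clipped_lo > clipped_hi and s_lo <= s_hi:
                note = (
                    f"mean {rs.mean.mean.value} is incompatible with item range "
                    f"[{lo}, {hi}] at n={n}"
                )
            s_lo, s_hi = clipped_lo, clipped_hi
    elif rs.item_range is not None:
        lo, hi = rs.item_range
        s_lo, s_hi = n * lo, n * hi
    else:
        # documented default: search |S/n| <= 10 * (sd + 1)
        bound = math.ceil(10 * (Fraction(rs.sd.value) + 1) * n)
        s_lo, s_hi = -bound, bound
    return range(s_lo, s_hi + 1), note


def _grimmer_neighbours(
    rs: ReportedSD, population_sd: bool, max_steps: int = 100
) -> tuple[Decimal | None, Decimal | None]:
    """Closest achievable printed SD values on either side of the reported one."""
    p = rs.sd.precision
    below = above = None
    for k in range(1, max_steps + 1):
        if below is None:
            cand = rs.sd.value - k * p
            if cand >= 0 and _sd_value_ok(cand, rs, population_sd):
                below = cand
        if above is None:
            cand = rs.sd.value + k * p
            if _sd_value_ok(cand, rs, population_sd):
                above = cand
        if (below is not None or rs.sd.value - k * p < 0) and above is not None:
            break
    return below, above


def _sd_value_ok(value: Decimal, rs: ReportedSD, population_sd: bool) -> bool:
    cand = ReportedSD(RoundedValue(value, rs.sd.precision), rs.n, rs.mean, rs.item_range)
    n = cand.n
    sd_lo, sd_hi = cand.sd.interval()
    sd_lo = max(sd_lo, Fraction(0))
    ddof = n if population_sd else n - 1
    var_lo, var_hi = sd_lo * sd_lo * ddof, sd_hi * sd_hi * ddof
    s_values, _ = _grimmer_sum_candidates(cand)
    for s in s_values:
        q_lo = math.ceil(Fraction(s * s, n) + var_lo)
        q_hi = math.floor(Fraction(s * s, n) + var_hi)
        for q in range(q_lo, q_hi + 1):
            if (q - s) % 2 == 0 and _feasible_multiset(n, s, q, cand.item_range) is not None:
                return True
    return False


# ---------------------------------------------------------------------------
# Exact feasibility of (n, sum, sum of squares) over bounded integers


def _near_equal_q(k: int, s: int) -> int:
    """Minimum sum of squares of k integers with sum s (near-equal partition)."""
    m, r = divmod(s, k)
    return (k - r) * m * m + r * (m + 1) * (m + 1)


def _extremal_q(k: int, s: int, lo: int, hi: int) -> int:
    """Maximum sum of squares of k integers in [lo, hi] with sum s."""
    if hi == lo:
        return k * lo * lo
    j, t = divmod(s - k * lo, hi - lo)
    if j >= k:
        return k * hi * hi
    return j * hi * hi + (k - j - 1) * lo * lo + (lo + t) * (lo + t)


def _feasible_multiset(
    n: int, s: int, q: int, item_range: tuple[int, int] | None
) -> dict[int, int] | None:
    """Multiset of n integers with sum s and sum of squares q, or None.

    When no item range is given, a finite search domain is derived from the
    fact that every value must lie within sqrt(q - s^2/n) of the mean.
    """
    spread = Fraction(q) - Fraction(s * s, n)
    if spread < 0:
        return None
    r = math.isqrt(math.ceil(spread)) + 1
    lo = math.ceil(Fraction(s, n)) - r
    hi = math.floor(Fraction(s, n)) + r
    if item_range is not None:
        lo, hi = max(lo, item_range[0]), min(hi, item_range[1])
    if hi < lo:
        return None
    if hi - lo > _MAX_DOMAIN:
        raise CapacityError(
            f"sum-of-squares feasibility domain [{lo}, {hi}] too large to search"
        )

    @lru_cache(maxsize=None)
    def rec(v: int, k: int, s_: int, q_: int) -> tuple[tuple[int, int], ...] | None:
        # choose counts for values lo..v; k items, sum s_, sum of squares q_ left
        if k == 0:
            return () if (s_ == 0 and q_ == 0) else None
        if s_ < k * lo or s_ > k * v:
            return None
        if q_ < _near_equal_q(k, s_) or q_ > _extremal_q(k, s_, lo, v):
            return None
        if v == lo:
            return ((lo, k),) if (s_ == k * lo and q_ == k * lo * lo) else None
        for c in range(k, -1, -1):
            rest = rec(v - 1, k - c, s_ - c * v, q_ - c * v * v)
            if rest is not None:
                return rest + ((v, c),) if c else rest
        return None

    counts = rec(hi, n, s, q)
    rec.cache_clear()
    if counts is None:
        return None
    return {value: count for value, count in counts}
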