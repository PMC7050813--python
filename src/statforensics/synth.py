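"""Seeded synthetic integer data and brute-force oracles.

The published studies this toolkit audits never released their raw data, so
every numerical claim the package makes is validated against data it
manufactures itself: small groups of integer survey-style responses drawn
from a discretized unimodal distribution.  From a known dataset the exact
mean/SD, their rounded versions, and the raw-data F statistic are all
available, which turns every check into a closed loop:

* rounded summaries of real integer data must always pass GRIM/GRIMMER;
* the reconstructed F from exact summaries must equal the raw-data F;
* the raw-data F must lie inside the rounding-perturbation bounds computed
  from two-decimal summaries.

All generation is driven by an explicit seed through one PRNG instance; there
is no global random state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import Decimal, localcontext
from fractions import Fraction

import numpy as np

from .anova import GroupSummary, RecomputedTest, _f_test
from .errors import CapacityError, InvalidInputError
from .rounding import RoundedValue, as_decimal, round_to_precision

__all__ = [
    "SyntheticGroup",
    "SyntheticDataset",
    "generate",
    "summarize",
    "exact_moments",
    "brute_force_reachable",
    "raw_f_oracle",
]


@dataclass(frozen=True)
class SyntheticGroup:
    label: str
    values: tuple[int, ...]


@dataclass(frozen=True)
class SyntheticDataset:
    """Reproducible integer dataset: same seed, same values, bit for bit."""

    seed: int
    item_range: tuple[int, int]
    groups: tuple[SyntheticGroup, ...]


def generate(
    seed: int,
    n_groups: int = 2,
    n_per_group: int = 20,
    item_range: tuple[int, int] = (1, 9),
    effects: list[float] | float | None = None,
    spread: float | None = None,
) -> SyntheticDataset:
    """Draw integer responses from a discretized, clipped normal distribution.

    Each group's responses are ``round(Normal(center + effect_g, spread))``
    clipped into ``item_range``; ``center`` is the midpoint of the range and
    ``spread`` defaults to a quarter of its width, giving the bell-shaped,
    slightly truncated response profiles typical of Likert-type items.
    ``effects`` is a per-group mean shift (scalar = same shift for all).
    """
    lo, hi = item_range
    if hi < lo:
        raise InvalidInputError(f"impossible item range {item_range}")
    if n_per_group < 2:
        raise InvalidInputError("n_per_group must be >= 2")
    if n_groups < 1:
        raise InvalidInputError("n_groups must be >= 1")
    if effects is None:
        shifts = [0.0] * n_groups
    elif np.isscalar(effects):
        shifts = [float(effects)] * n_groups
    else:
        shifts = [float(e) for e in effects]
        if len(shifts) != n_groups:
            raise InvalidInputError("effects must have one entry per group")
    center = (lo + hi) / 2.0
    scale = spread if spread is not None else max((hi - lo) / 4.0, 0.5)
    rng = np.random.default_rng(seed)
    groups = []
    for g, shift in enumerate(shifts):
        raw = rng.normal(center + shift, scale, size=n_per_group)
        values = np.clip(np.rint(raw), lo, hi).astype(int)
        groups.append(SyntheticGroup(label=f"g{g + 1}", values=tuple(int(v) for v in values)))
    return SyntheticDataset(seed=seed, item_range=(lo, hi), groups=tuple(groups))


def exact_moments(ds: SyntheticDataset) -> list[tuple[int, Fraction, Fraction]]:
    """Per group: (n, exact mean, exact sample variance) as rationals."""
    out = []
    for g in ds.groups:
        n = len(g.values)
        s = sum(g.values)
        q = sum(v * v for v in g.values)
        mean = Fraction(s, n)
        var = Fraction(n * q - s * s, n * (n - 1)) if n > 1 else Fraction(0)
        out.append((n, mean, var))
    return out


def summarize(ds: SyntheticDataset, precision: Decimal | str = Decimal("0.01")) -> list[GroupSummary]:
    """Group summaries with mean and sample SD rounded half-away-from-zero.

    This mimics what a publication prints: the exact statistics pushed onto a
    decimal grid.  The SD square root is evaluated at 50 significant digits
    before quantizing, so the printed value is the true rounding except on
    (measure-zero) exact midpoints of irrational SDs, which cannot occur.
    """
    precision = as_decimal(precision)
    out = []
    for g, (n, mean, var) in zip(ds.groups, exact_moments(ds)):
        mean_r = round_to_precision(mean, precision)
        with localcontext() as ctx:
            ctx.prec = 50
            sd_exact = (Decimal(var.numerator) / Decimal(var.denominator)).sqrt()
        sd_r = round_to_precision(Fraction(sd_exact), precision)
        out.append(GroupSummary(
            g.label, n, RoundedValue(mean_r, precision), RoundedValue(sd_r, precision)
        ))
    return out


def brute_force_reachable(
    n: int,
    item_range: tuple[int, int],
    precision: Decimal | str = Decimal("0.01"),
    guard: int = 5_000_000,
) -> set[tuple[Decimal, Decimal | None]]:
    """Exact set of achievable rounded (mean, sd) pairs by multiset enumeration.

    The oracle for GRIM/GRIMMER.  Enumerates every multiset of ``n`` integers
    in ``item_range`` (order-free — mean and SD are permutation invariant),
    and for each collects every printed (mean, sd) pair it can round to under
    the inclusive both-ways midpoint convention.  For ``n = 1`` the sd slot
    is ``None``.  Refuses enumerations beyond ``guard`` multisets.
    """
    lo, hi = item_range
    if hi < lo:
        raise InvalidInputError(f"impossible item range {item_range}")
    precision = as_decimal(precision)
    r = hi - lo
    count = math.comb(n + r, r)
    if count > guard:
        raise CapacityError(
            f"{count} multisets of size {n} over [{lo}, {hi}] exceeds the "
            f"enumeration guard of {guard}"
        )
    half = Fraction(precision) / 2
    p_frac = Fraction(precision)
    out: set[tuple[Decimal, Decimal | None]] = set()
    for combo in itertools.combinations_with_replacement(range(lo, hi + 1), n):
        s = sum(combo)
        mean = Fraction(s, n)
        mean_roundings = _roundings(mean, precision)
        if n == 1:
            out.update((m, None) for m in mean_roundings)
            continue
        q = sum(v * v for v in combo)
        var = Fraction(n * q - s * s, n * (n - 1))
        # printed sd g is achievable iff max(g - p/2, 0)^2 <= var <= (g + p/2)^2
        sd_approx = math.sqrt(var)
        k0 = round(sd_approx / float(p_frac))
        sd_roundings = []
        for k in range(max(k0 - 2, 0), k0 + 3):
            g = Fraction(k) * p_frac
            g_lo = max(g - half, Fraction(0))
            if g_lo * g_lo <= var <= (g + half) * (g + half):
                sd_roundings.append(Decimal(k) * precision)
        out.update((m, sd) for m in mean_roundings for sd in sd_roundings)
    return out


def _roundings(x: Fraction, precision: Decimal) -> list[Decimal]:
    p = Fraction(precision)
    k0 = math.floor(x / p)
    out = []
    for k in (k0 - 1, k0, k0 + 1):
        if abs(x - k * p) * 2 <= p:
            out.append(Decimal(k) * precision)
    return out


def raw_f_oracle(ds: SyntheticDataset) -> RecomputedTest:
    """Textbook one-way ANOVA computed directly from the raw values.

    The independent check for the summary-statistics reconstruction: sums of
    squares are accumulated from individual observations, never from means
    and SDs.
    """
    if len(ds.groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    if any(len(g.values) < 2 for g in ds.groups):
        raise InvalidInputError("every group needs n >= 2")
    arrays = [np.asarray(g.values, dtype=float) for g in ds.groups]
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = all_values.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return _f_test(0.0, df1, df2, False)
        return _f_test(math.inf, df1, df2, True)
    f = (ss_between / df1) / (ss_within / df2)
    return _f_test(f, df1, df2, False)
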