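"""Reconstruction of t and F statistics from published summary statistics.

Given per-cell sample sizes, means and SDs it is possible to recompute the
test statistics of t tests and one- or two-way between-subjects ANOVAs without
the raw data.  Because the published means and SDs are themselves rounded,
:func:`stat_bounds` propagates the reporting precision through the
reconstruction: the upper bound shrinks every SD by half a printing step and
tries every combination of perturbed means, the lower bound does the reverse.
A reported statistic is treated as consistent when its own rounding interval
intersects the resulting bounds — a deliberately conservative criterion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import Decimal

from scipy import stats

from .consistency import Finding
from .errors import CapacityError, InvalidInputError
from .rounding import RoundedValue, as_decimal, infer_precision

__all__ = [
    "GroupSummary",
    "FactorialGrid",
    "RecomputedTest",
    "StatBounds",
    "TwoWayResult",
    "oneway_f",
    "pooled_t",
    "twoway_f",
    "stat_bounds",
    "p_agreement",
    "bounds_verdict",
]


@dataclass(frozen=True)
class GroupSummary:
    """One cell of a design: sample size, mean and SD as reported."""

    label: str
    n: int
    mean: RoundedValue
    sd: RoundedValue

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"group {self.label!r}: n >= 2 required, got {self.n}")
        if self.sd.value < 0:
            raise InvalidInputError(f"group {self.label!r}: negative SD")

    @classmethod
    def make(cls, label: str, n: int, mean, sd, precision="0.01") -> "GroupSummary":
        p = as_decimal(precision)
        return cls(label, n, RoundedValue(as_decimal(mean), p), RoundedValue(as_decimal(sd), p))


@dataclass(frozen=True)
class FactorialGrid:
    """Complete two-factor between-subjects design of cell summaries.

    ``cells[i][j]`` is the cell at level i of factor A and level j of factor B.
    """

    factor_a_levels: tuple[str, ...]
    factor_b_levels: tuple[str, ...]
    cells: tuple[tuple[GroupSummary, ...], ...]

    def __post_init__(self) -> None:
        a, b = len(self.factor_a_levels), len(self.factor_b_levels)
        if a < 2 or b < 2:
            raise InvalidInputError("both factors need at least 2 levels")
        if len(self.cells) != a or any(len(row) != b for row in self.cells):
            raise InvalidInputError("factorial grid has a missing or extra cell")

    def flat(self) -> list[GroupSummary]:
        return [c for row in self.cells for c in row]


@dataclass(frozen=True)
class RecomputedTest:
    """A reconstructed t or F statistic with its p value.

    ``overflow`` marks the degenerate all-variances-zero case with unequal
    means, where the statistic is unbounded (reported as ``inf`` with p = 0).
    """

    family: str  # "t" or "F"
    statistic: float
    df1: int
    df2: int
    p: float
    overflow: bool = False


@dataclass(frozen=True)
class StatBounds:
    """Extreme values a statistic can take given reporting precision."""

    lower: float
    upper: float
    perturbation: Decimal = Decimal("0.005")

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InvalidInputError("bounds require lower <= upper")


@dataclass(frozen=True)
class TwoWayResult:
    main_a: RecomputedTest
    main_b: RecomputedTest
    interaction: RecomputedTest


# ---------------------------------------------------------------------------
# numeric cores (plain floats; called both on exact summaries and on
# perturbed values during bound enumeration)


def _oneway_core(ns, means, sds) -> tuple[float, int, int, bool]:
    k = len(ns)
    n_total = sum(ns)
    df1, df2 = k - 1, n_total - k
    grand = sum(n * m for n, m in zip(ns, means)) / n_total
    ss_between = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ss_within = sum((n - 1) * s * s for n, s in zip(ns, sds))
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, df1, df2, False
        return math.inf, df1, df2, True
    return ms_between / ms_within, df1, df2, False


def _pooled_t_core(ns, means, sds) -> float:
    n1, n2 = ns
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sds[0] ** 2 + (n2 - 1) * sds[1] ** 2) / df
    se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    diff = means[0] - means[1]
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(se2)


def _twoway_core(ns, means, sds, method: str) -> dict[str, tuple[float, int, int, bool]]:
    """ns/means/sds are a x b nested lists; returns per-effect (F, df1, df2, overflow)."""
    a, b = len(ns), len(ns[0])
    n_total = sum(sum(row) for row in ns)
    df_err = n_total - a * b
    if df_err <= 0:
        raise InvalidInputError("no error degrees of freedom")
    ss_err = sum((ns[i][j] - 1) * sds[i][j] ** 2 for i in range(a) for j in range(b))
    ms_err = ss_err / df_err

    if method == "unweighted":
        n_h = (a * b) / sum(1.0 / ns[i][j] for i in range(a) for j in range(b))
        grand = sum(means[i][j] for i in range(a) for j in range(b)) / (a * b)
        a_m = [sum(means[i][j] for j in range(b)) / b for i in range(a)]
        b_m = [sum(means[i][j] for i in range(a)) / a for j in range(b)]
        ss_a = n_h * b * sum((am - grand) ** 2 for am in a_m)
        ss_b = n_h * a * sum((bm - grand) ** 2 for bm in b_m)
        ss_ab = n_h * sum(
            (means[i][j] - a_m[i] - b_m[j] + grand) ** 2
            for i in range(a)
            for j in range(b)
        )
    else:
        grand = sum(ns[i][j] * means[i][j] for i in range(a) for j in range(b)) / n_total
        a_n = [sum(ns[i]) for i in range(a)]
        b_n = [sum(ns[i][j] for i in range(a)) for j in range(b)]
        a_m = [sum(ns[i][j] * means[i][j] for j in range(b)) / a_n[i] for i in range(a)]
        b_m = [sum(ns[i][j] * means[i][j] for i in range(a)) / b_n[j] for j in range(b)]
        ss_a = sum(a_n[i] * (a_m[i] - grand) ** 2 for i in range(a))
        ss_b = sum(b_n[j] * (b_m[j] - grand) ** 2 for j in range(b))
        ss_ab = sum(
            ns[i][j] * (means[i][j] - a_m[i] - b_m[j] + grand) ** 2
            for i in range(a)
            for j in range(b)
        )

    def effect(ss: float, df: int) -> tuple[float, int, int, bool]:
        if ms_err == 0.0:
            return (0.0, df, df_err, False) if ss == 0.0 else (math.inf, df, df_err, True)
        return ss / df / ms_err, df, df_err, False

    return {
        "A": effect(ss_a, a - 1),
        "B": effect(ss_b, b - 1),
        "interaction": effect(ss_ab, (a - 1) * (b - 1)),
    }


def _f_test(f: float, df1: int, df2: int, overflow: bool) -> RecomputedTest:
    if overflow:
        p = 0.0
    elif f == 0.0:
        p = 1.0
    else:
        p = float(stats.f.sf(f, df1, df2))
    return RecomputedTest("F", f, df1, df2, p, overflow)


# ---------------------------------------------------------------------------
# public reconstruction API


def oneway_f(groups: list[GroupSummary]) -> RecomputedTest:
    """One-way between-subjects ANOVA F from group summaries.

    Between mean square from n-weighted squared deviations of group means
    about the weighted grand mean over k-1; within mean square pools the
    group variances with weights n_i - 1; df = (k-1, N-k).
    """
    if len(groups) < 2:
        raise InvalidInputError("one-way ANOVA needs at least 2 groups")
    ns = [g.n for g in groups]
    means = [float(g.mean.value) for g in groups]
    sds = [float(g.sd.value) for g in groups]
    return _f_test(*_oneway_core(ns, means, sds))


def pooled_t(g1: GroupSummary, g2: GroupSummary, tails: int = 2) -> RecomputedTest:
    """Pooled-variance two-sample t; its square equals the two-group F."""
    if tails not in (1, 2):
        raise InvalidInputError("tails must be 1 or 2")
    df = g1.n + g2.n - 2
    t = _pooled_t_core(
        [g1.n, g2.n],
        [float(g1.mean.value), float(g2.mean.value)],
        [float(g1.sd.value), float(g2.sd.value)],
    )
    if math.isinf(t):
        return RecomputedTest("t", t, 1, df, 0.0, overflow=True)
    p = float(tails * stats.t.sf(abs(t), df)) if t != 0.0 else 1.0
    return RecomputedTest("t", t, 1, df, min(p, 1.0))


def twoway_f(grid: FactorialGrid, method: str = "unweighted") -> TwoWayResult:
    """Two-way between-subjects ANOVA from cell summaries.

    The default is the unweighted-(cell)-means analysis: effect sums of
    squares use the cell means weighted equally, scaled by the harmonic mean
    of the cell sizes, with the error term pooled within cells; DFs are
    (a-1), (b-1) and (a-1)(b-1) over N - ab.  For balanced designs this
    coincides with the textbook analysis.  ``method="weighted"`` weights cell
    means by their sample sizes instead (published tables rarely state which
    analysis produced them).
    """
    if method not in ("unweighted", "weighted"):
        raise InvalidInputError(f"unknown method {method!r}")
    ns = [[c.n for c in row] for row in grid.cells]
    means = [[float(c.mean.value) for c in row] for row in grid.cells]
    sds = [[float(c.sd.value) for c in row] for row in grid.cells]
    effects = _twoway_core(ns, means, sds, method)
    return TwoWayResult(
        main_a=_f_test(*effects["A"]),
        main_b=_f_test(*effects["B"]),
        interaction=_f_test(*effects["interaction"]),
    )


# ---------------------------------------------------------------------------
# rounding-error bounds


def stat_bounds(
    groups_or_grid,
    selector: str = "F",
    perturbation: Decimal | str = Decimal("0.005"),
    method: str = "unweighted",
) -> StatBounds:
    """Extreme statistic values under reporting-precision perturbation.

    Every mean is shifted by +/- ``perturbation`` in all 2^cells combinations
    (enumerated exhaustively, as a mean's effect on the statistic is not
    monotone); SDs are all shifted down for the upper bound and up for the
    lower bound, which is exact because the statistic is monotone in each SD.
    SDs are floored at zero after downward perturbation.

    ``selector``: "F" or "t" for a list of groups; "A", "B" or "interaction"
    for a :class:`FactorialGrid`.
    """
    pert = as_decimal(perturbation)
    if pert < 0:
        raise InvalidInputError("perturbation must be >= 0")
    eps = float(pert)

    if isinstance(groups_or_grid, FactorialGrid):
        grid = groups_or_grid
        cells = grid.flat()
        if selector not in ("A", "B", "interaction"):
            raise InvalidInputError(f"selector {selector!r} invalid for a factorial grid")
        shape = [len(row) for row in grid.cells]
        ns_nested = [[c.n for c in row] for row in grid.cells]

        def nest(flat):
            out, k = [], 0
            for width in shape:
                out.append(list(flat[k:k + width]))
                k += width
            return out

        def evaluate(means, sds):
            effects = _twoway_core(ns_nested, nest(means), nest(sds), method)
            return effects[selector][0]
    else:
        cells = list(groups_or_grid)
        if len(cells) < 2:
            raise InvalidInputError("need at least 2 groups")
        if selector not in ("F", "t"):
            raise InvalidInputError(f"selector {selector!r} invalid for a group list")
        if selector == "t" and len(cells) != 2:
            raise InvalidInputError("t bounds require exactly 2 groups")
        ns_flat = [g.n for g in cells]

        def evaluate(means, sds):
            if selector == "F":
                return _oneway_core(ns_flat, means, sds)[0]
            return _pooled_t_core(ns_flat, means, sds)

    if len(cells) > 20:
        raise CapacityError(
            f"{len(cells)} cells would require {2 ** len(cells)} mean combinations; "
            "refusing exhaustive enumeration beyond 20 cells"
        )

    base_means = [float(c.mean.value) for c in cells]
    base_sds = [float(c.sd.value) for c in cells]
    upper = -math.inf
    lower = math.inf
    for signs in itertools.product((-eps, eps), repeat=len(cells)):
        means = [m + s for m, s in zip(base_means, signs)]
        upper = max(upper, evaluate(means, [max(0.0, s - eps) for s in base_sds]))
        lower = min(lower, evaluate(means, [s + eps for s in base_sds]))
    return StatBounds(lower=lower, upper=upper, perturbation=pert)


# ---------------------------------------------------------------------------
# agreement verdicts


def _parse_reported_p(reported_p) -> tuple[str, Decimal]:
    if isinstance(reported_p, tuple):
        op, value = reported_p
        return op, as_decimal(value)
    text = str(reported_p).strip()
    op = "="
    if text and text[0] in "<>=":
        op = text[0]
        text = text[1:].strip()
    return op, Decimal(text)


def p_agreement(
    rt: RecomputedTest,
    reported_p,
    p_precision: Decimal | str | None = None,
) -> Finding:
    """Is a reported p value consistent with the recomputed statistic?

    ``reported_p`` is a decimal (or string such as ``"0.04"``), or an
    inequality such as ``"< 0.01"``.  An equality is consistent when the
    recomputed p, rounded at ``p_precision`` (inclusive endpoints, default:
    the precision at which the reported p is printed), can equal the reported
    value; an inequality is consistent when the recomputed p satisfies it.
    """
    op, value = _parse_reported_p(reported_p)
    if not (0 <= value <= 1):
        raise InvalidInputError(f"p value {value} outside [0, 1]")
    p = rt.p
    if op == "=":
        prec = as_decimal(p_precision) if p_precision is not None else infer_precision(str(value))
        ok = abs(p - float(value)) <= float(prec) / 2
    elif op == "<":
        ok = p < float(value)
    elif op == ">":
        ok = p > float(value)
    else:
        raise InvalidInputError(f"unknown p comparison {op!r}")
    return Finding(
        check="p_agreement",
        location="",
        reported=f"p {op} {value}",
        recomputed=f"{p:.6g}",
        severity="consistent" if ok else "inconsistent",
        message=(
            f"recomputed p = {p:.4g} for {rt.family}({rt.df1},{rt.df2}) = "
            f"{rt.statistic:.4g}; reported p {op} {value} is "
            f"{'consistent' if ok else 'inconsistent'}"
        ),
    )


def bounds_verdict(
    reported_stat: RoundedValue | Decimal | str,
    bounds: StatBounds,
    stat_precision: Decimal | str = Decimal("0.01"),
) -> Finding:
    """Does a reported statistic's rounding interval intersect its bounds?"""
    if isinstance(reported_stat, RoundedValue):
        rv = reported_stat
    else:
        rv = RoundedValue(as_decimal(reported_stat), as_decimal(stat_precision))
    lo, hi = rv.interval()
    ok = float(lo) <= bounds.upper and float(hi) >= bounds.lower
    return Finding(
        check="bounds_verdict",
        location="",
        reported=str(rv.value),
        recomputed=f"[{bounds.lower:.6g}, {bounds.upper:.6g}]",
        severity="consistent" if ok else "inconsistent",
        message=(
            f"reported {rv.value} {'falls within' if ok else 'falls outside'} "
            f"possible range [{bounds.lower:.4f}, {bounds.upper:.4f}]"
        ),
    )
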