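"""Arithmetic audits across reported counts and tables.

These checks need no statistics at all, only bookkeeping: cumulative
("at least k") counts must difference to nonnegative exact counts, subgroup
sizes must add up to stated totals, a subset of a sample can never contain a
larger group than its superset, two renderings of the same table must agree
cell for cell, and a value converted between units must stay inside the
interval its rounded source allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import Literal, Mapping, Sequence

from .errors import InvalidInputError
from .rounding import RoundedValue, as_decimal

__all__ = [
    "Severity",
    "Finding",
    "CumulativeCounts",
    "CumulativeResult",
    "LabeledTable",
    "TableDiff",
    "exact_from_cumulative",
    "sum_check",
    "subset_check",
    "partition_min_max",
    "cross_table_diff",
    "conversion_interval",
    "conversion_verdict",
    "KG_TO_LB",
    "CM_TO_IN",
]

Severity = Literal["impossible", "inconsistent", "consistent"]

# default conversion factors; the factor a source article used is usually
# unknown, so verdicts can be re-run with e.g. 2.2 to probe sensitivity
KG_TO_LB = Decimal("2.2046226218")
CM_TO_IN = Decimal("0.3937007874")


@dataclass
class Finding:
    """One consistency verdict linking a reported value to its recomputation."""

    check: str
    location: str
    reported: str
    recomputed: str
    severity: Severity
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "check": self.check,
            "location": self.location,
            "reported": self.reported,
            "recomputed": self.recomputed,
            "severity": self.severity,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Finding":
        return cls(
            check=d["check"], location=d["location"], reported=d["reported"],
            recomputed=d["recomputed"], severity=d["severity"],
            message=d.get("message", ""),
        )


@dataclass(frozen=True)
class CumulativeCounts:
    """Counts of cases meeting ascending thresholds (e.g. ate >= 1, 2, 3 slices)."""

    thresholds: tuple[int, ...]
    at_least: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.at_least):
            raise InvalidInputError("thresholds and at_least must have equal length")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise InvalidInputError("thresholds must be strictly ascending")
        # a weakly increasing at_least sequence is reported as a finding, not an error


@dataclass
class CumulativeResult:
    exact: list[int]
    findings: list[Finding] = field(default_factory=list)


def exact_from_cumulative(c: CumulativeCounts, location: str = "") -> CumulativeResult:
    """Exact per-threshold counts by differencing cumulative counts.

    ``exact[i] = at_least[i] - at_least[i+1]`` with the last bin passed
    through.  The exact counts always sum to ``at_least[0]``.  A cumulative
    count that *increases* implies a negative exact count, which is reported
    as an impossible finding rather than raising.
    """
    al = list(c.at_least)
    exact = [al[i] - al[i + 1] for i in range(len(al) - 1)] + [al[-1]]
    findings = []
    for i, e in enumerate(exact[:-1]):
        if e < 0:
            findings.append(Finding(
                check="exact_from_cumulative",
                location=location,
                reported=f"at_least[{c.thresholds[i]}]={al[i]}, "
                         f"at_least[{c.thresholds[i + 1]}]={al[i + 1]}",
                recomputed=str(e),
                severity="impossible",
                message=(
                    f"count of cases at threshold {c.thresholds[i + 1]} exceeds the "
                    f"count at threshold {c.thresholds[i]}: exact count would be {e}"
                ),
            ))
    return CumulativeResult(exact=exact, findings=findings)


def sum_check(parts: Sequence[int], stated_total: int, location: str = "") -> Finding:
    """Do subgroup counts add up to the stated total?"""
    total = sum(parts)
    ok = total == stated_total
    return Finding(
        check="sum_check",
        location=location,
        reported=str(stated_total),
        recomputed=str(total),
        severity="consistent" if ok else "inconsistent",
        message=(
            f"parts {tuple(parts)} sum to {total}; stated total is {stated_total}"
        ),
    )


def subset_check(
    sub: Mapping[str, int], superset: Mapping[str, int], location: str = ""
) -> list[Finding]:
    """Groups of a subsample can never exceed the matching superset groups.

    Returns one inconsistent finding per shared label where sub > superset;
    the violation count is the length of the returned list.
    """
    if set(sub) != set(superset):
        raise InvalidInputError(
            f"label mismatch: {sorted(set(sub) ^ set(superset))}"
        )
    findings = []
    for label in sub:
        if sub[label] > superset[label]:
            findings.append(Finding(
                check="subset_check",
                location=location,
                reported=f"{label}: subset {sub[label]}",
                recomputed=f"{label}: superset {superset[label]}",
                severity="inconsistent",
                message=(
                    f"group {label!r} has {sub[label]} cases in the subset but only "
                    f"{superset[label]} in the superset it was drawn from"
                ),
            ))
    return findings


def partition_min_max(total: int, parts: int) -> int:
    """Smallest possible maximum when partitioning ``total`` into ``parts``.

    Whatever the split of ``total`` cases over ``parts`` groups, at least one
    group holds ``ceil(total/parts)`` or more.
    """
    if parts < 1:
        raise InvalidInputError(f"parts must be >= 1, got {parts}")
    if total < 0:
        raise InvalidInputError(f"total must be >= 0, got {total}")
    return math.ceil(total / parts)


@dataclass(frozen=True)
class LabeledTable:
    """A transcribed published table; cell values kept as printed text."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        if len(set(self.row_labels)) != len(self.row_labels):
            raise InvalidInputError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise InvalidInputError("duplicate column labels")


@dataclass
class TableDiff:
    findings: list[Finding]
    only_in_first: list[tuple[str, str]]
    only_in_second: list[tuple[str, str]]


def cross_table_diff(
    t1: LabeledTable,
    t2: LabeledTable,
    tolerance: Decimal | str = Decimal("0"),
    location: str = "",
) -> TableDiff:
    """Cell-by-cell comparison of two renderings of the same table.

    Two tables that re-present the same summary statistics must agree exactly,
    so the default tolerance is zero (decimal equality); a tolerance is
    opt-in.  Cells present in only one table are reported separately, not as
    value findings.
    """
    tol = Fraction(as_decimal(tolerance))
    keys1 = {(r, c) for r in t1.row_labels for c in t1.col_labels if (r, c) in t1.cells}
    keys2 = {(r, c) for r in t2.row_labels for c in t2.col_labels if (r, c) in t2.cells}
    shared = sorted(keys1 & keys2)
    findings = []
    for key in shared:
        v1, v2 = Fraction(Decimal(t1.cells[key])), Fraction(Decimal(t2.cells[key]))
        if abs(v1 - v2) > tol:
            findings.append(Finding(
                check="cross_table_diff",
                location=location or f"{key[0]} / {key[1]}",
                reported=t1.cells[key],
                recomputed=t2.cells[key],
                severity="inconsistent",
                message=(
                    f"cell ({key[0]!r}, {key[1]!r}) differs between tables: "
                    f"{t1.cells[key]} versus {t2.cells[key]}"
                ),
            ))
    return TableDiff(
        findings=findings,
        only_in_first=sorted(keys1 - keys2),
        only_in_second=sorted(keys2 - keys1),
    )


def conversion_interval(
    value: RoundedValue, factor: Decimal | str
) -> tuple[Fraction, Fraction]:
    """Interval a rounded source value maps to under a unit conversion."""
    f = Fraction(as_decimal(factor))
    if f <= 0:
        raise InvalidInputError("conversion factor must be > 0")
    lo, hi = value.interval()
    return (lo * f, hi * f)


def conversion_verdict(
    reported: RoundedValue,
    source: RoundedValue,
    factor: Decimal | str,
    location: str = "",
) -> Finding:
    """Is a converted value consistent with its rounded source?

    Consistent iff the reported value's rounding interval intersects the
    image of the source interval under the conversion factor.
    """
    lo, hi = conversion_interval(source, factor)
    r_lo, r_hi = reported.interval()
    ok = r_lo <= hi and r_hi >= lo
    return Finding(
        check="conversion_verdict",
        location=location,
        reported=str(reported.value),
        recomputed=f"[{float(lo):.4f}, {float(hi):.4f}]",
        severity="consistent" if ok else "inconsistent",
        message=(
            f"source {source.value} x {factor} allows "
            f"[{float(lo):.4f}, {float(hi):.4f}]; reported {reported.value} is "
            f"{'consistent' if ok else 'inconsistent'}"
        ),
    )
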