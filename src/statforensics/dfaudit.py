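"""Degrees-of-freedom audits: the sample size a reported test implies.

For the common designs, the denominator DF of a t or F statistic pins down
the total sample size exactly:

* one-way between-subjects, k groups:  N = df2 + k
* a x b factorial between-subjects:    N = df2 + a*b
* repeated measures, k conditions:     subjects n = df2/df1 + 1
* regression with k predictors:        N = df2 + df1 + 1  (intercept fitted)

An implied N *larger* than the stated sample size is impossible — no analysis
can have more error DF than cases.  A *smaller* implied N is only flagged as a
soft inconsistency, because statistical software silently drops incomplete
cases (listwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

from .consistency import Finding
from .errors import InvalidInputError, ShapeError

__all__ = ["DesignSpec", "ReportedDF", "implied_n", "expected_df", "df_verdict"]

_KINDS = ("oneway_between", "factorial_between", "repeated_measures", "regression")


@dataclass(frozen=True)
class DesignSpec:
    """The statistical design a reported DF pair is audited against.

    ``k`` is the group count (one-way), the pair of level counts (factorial),
    the number of within-subject conditions (repeated measures), or the
    number of predictors (regression).
    """

    kind: str
    k: int | tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown design kind {self.kind!r}")
        if self.kind == "factorial_between":
            if not (isinstance(self.k, tuple) and len(self.k) == 2):
                raise InvalidInputError("factorial design needs k = (a, b)")
            if min(self.k) < 2:
                raise InvalidInputError("factor level counts must be >= 2")
        else:
            if not isinstance(self.k, int):
                raise InvalidInputError(f"{self.kind} needs an integer k")
            minimum = 1 if self.kind == "regression" else 2
            if self.k < minimum:
                raise InvalidInputError(f"{self.kind} needs k >= {minimum}")


@dataclass(frozen=True)
class ReportedDF:
    df1: int
    df2: int

    def __post_init__(self) -> None:
        if self.df1 < 1 or self.df2 < 0:
            raise InvalidInputError(f"invalid DF pair ({self.df1}, {self.df2})")


def _factorial_effect_df1s(a: int, b: int) -> dict[str, int]:
    return {"A": a - 1, "B": b - 1, "interaction": (a - 1) * (b - 1)}


def implied_n(df: ReportedDF, design: DesignSpec) -> int:
    """Sample size (or subject count, for repeated measures) implied by a DF pair.

    Raises :class:`ShapeError` when df1 cannot belong to the design, and
    :class:`InvalidInputError` for a repeated-measures df2 that is not a
    multiple of df1 (no integer number of subjects can produce it).
    """
    if design.kind == "oneway_between":
        k = design.k
        if df.df1 != k - 1:
            raise ShapeError(f"one-way with k={k} has df1={k - 1}, not {df.df1}")
        return df.df2 + k
    if design.kind == "factorial_between":
        a, b = design.k
        if df.df1 not in _factorial_effect_df1s(a, b).values():
            raise ShapeError(
                f"{a}x{b} factorial effects have df1 in "
                f"{sorted(set(_factorial_effect_df1s(a, b).values()))}, not {df.df1}"
            )
        return df.df2 + a * b
    if design.kind == "repeated_measures":
        k = design.k
        if df.df1 != k - 1:
            raise ShapeError(f"repeated measures with k={k} has df1={k - 1}, not {df.df1}")
        if df.df2 % df.df1 != 0:
            raise InvalidInputError(
                f"df2={df.df2} is not a multiple of df1={df.df1}: "
                "no integer subject count fits"
            )
        return df.df2 // df.df1 + 1
    # regression (with intercept)
    if df.df1 != design.k:
        raise ShapeError(f"regression with {design.k} predictors has df1={design.k}, not {df.df1}")
    return df.df2 + df.df1 + 1


def expected_df(design: DesignSpec, n: int, effect: str = "A") -> ReportedDF:
    """DF pair a design should report at sample size ``n`` (inverse of implied_n).

    For factorial designs ``effect`` selects the numerator: "A", "B" or
    "interaction".
    """
    if design.kind == "oneway_between":
        df1, df2 = design.k - 1, n - design.k
    elif design.kind == "factorial_between":
        a, b = design.k
        effects = _factorial_effect_df1s(a, b)
        if effect not in effects:
            raise InvalidInputError(f"effect must be one of {sorted(effects)}")
        df1, df2 = effects[effect], n - a * b
    elif design.kind == "repeated_measures":
        df1, df2 = design.k - 1, (design.k - 1) * (n - 1)
    else:
        df1, df2 = design.k, n - design.k - 1
    if df2 <= 0:
        raise InvalidInputError(
            f"n={n} leaves no error degrees of freedom for {design.kind} design"
        )
    return ReportedDF(df1, df2)


def df_verdict(df: ReportedDF, design: DesignSpec, stated_n: int, location: str = "") -> Finding:
    """Compare the sample size implied by a DF pair with the stated one.

    Severity is "impossible" when the implied N exceeds the stated N (more
    error DF than cases), "inconsistent" when smaller (conceivably listwise
    deletion), "consistent" when equal.  For regressions, the message notes
    when the discrepancy disappears under the no-intercept DF convention.
    """
    try:
        implied = implied_n(df, design)
    except (ShapeError, InvalidInputError) as exc:
        return Finding(
            check="df_verdict",
            location=location,
            reported=f"({df.df1},{df.df2}) with stated N={stated_n}",
            recomputed="-",
            severity="impossible",
            message=str(exc),
        )
    unit = "subjects" if design.kind == "repeated_measures" else "N"
    if implied == stated_n:
        severity: str = "consistent"
        message = f"DFs ({df.df1},{df.df2}) imply {unit}={implied}, matching the stated {stated_n}"
    elif implied > stated_n:
        severity = "impossible"
        message = (
            f"DFs ({df.df1},{df.df2}) imply {unit}={implied}, which exceeds the "
            f"stated {stated_n}"
        )
    else:
        severity = "inconsistent"
        message = (
            f"DFs ({df.df1},{df.df2}) imply {unit}={implied}, smaller than the stated "
            f"{stated_n} (possible via listwise deletion)"
        )
    if design.kind == "regression" and implied != stated_n:
        no_intercept = df.df2 + df.df1
        if no_intercept == stated_n:
            message += (
                f"; under a no-intercept convention the implied N would be "
                f"{no_intercept}, matching the stated total"
            )
    return Finding(
        check="df_verdict",
        location=location,
        reported=f"({df.df1},{df.df2}) with stated N={stated_n}",
        recomputed=str(implied),
        severity=severity,  # type: ignore[arg-type]
        message=message,
    )
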