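"""Fixture formats, APA statistic-string parsing, and audit reports.

Transcribed statistics enter the package through a small CSV/JSON row schema.
Decimals are carried as *text* end to end: "1.20" and "1.2" are different
claims (two- versus one-decimal precision), and precision is a semantic input
to every granularity check, so values must never pass through binary floats.

CSV schema (header must match exactly)::

    article,table,row_label,group_label,n,mean,sd,precision,checks

``precision`` may be left blank to infer it from the printed mean/sd; ``checks``
is a ``;``-separated subset of {grim, grimmer, f, t}.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Iterable, Sequence

from .consistency import Finding
from .errors import InvalidInputError, ParseError
from .granularity import ReportedMean, ReportedSD, grim_check, grimmer_check
from .anova import GroupSummary, RecomputedTest, oneway_f, pooled_t, stat_bounds
from .rounding import RoundedValue, as_decimal, infer_precision

__all__ = [
    "FixtureRow",
    "FixtureSet",
    "AuditConfig",
    "AuditReport",
    "parse_apa",
    "load_fixtures",
    "dump_fixtures",
    "run_audit",
    "render",
    "CSV_HEADER",
]

CSV_HEADER = ["article", "table", "row_label", "group_label", "n", "mean", "sd",
              "precision", "checks"]
_KNOWN_CHECKS = ("grim", "grimmer", "f", "t")


@dataclass(frozen=True)
class FixtureRow:
    """One transcribed cell: a group's n/mean/SD with its provenance."""

    article: str
    table: str
    row_label: str
    group_label: str
    n: int | None = None
    mean: str | None = None   # as printed, trailing zeros intact
    sd: str | None = None
    precision: Decimal | None = None
    checks: tuple[str, ...] = ("grim",)

    @property
    def location(self) -> str:
        parts = [self.article, self.table, self.row_label]
        if self.group_label:
            parts.append(self.group_label)
        return " / ".join(p for p in parts if p)

    def mean_value(self) -> RoundedValue | None:
        if self.mean is None or self.mean == "":
            return None
        return RoundedValue.from_text(self.mean, self.precision)

    def sd_value(self) -> RoundedValue | None:
        if self.sd is None or self.sd == "":
            return None
        return RoundedValue.from_text(self.sd, self.precision)


@dataclass
class FixtureSet:
    rows: list[FixtureRow]
    errors: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# APA statistic strings

_APA_RE = re.compile(
    r"""^\s*(?P<family>[FtT])\s*
        [\(\[]\s*(?P<df1>\d+)\s*(?:,\s*(?P<df2>\d+)\s*)?[\)\]]\s*
        =\s*(?P<stat>-?\d+(?:\.\d+)?)\s*
        (?:[;,]\s*[pP]\s*(?P<op>[=<>])\s*(?P<p>\.?\d+(?:\.\d+)?)\s*)?
        $""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class ReportedTest:
    """A published test statistic as transcribed from an article."""

    family: str                 # "t" or "F"
    statistic: Decimal
    df1: int
    df2: int
    p: Decimal | None = None
    p_op: str = "="             # "=", "<" or ">"

    @property
    def p_text(self) -> str | None:
        if self.p is None:
            return None
        return f"p {self.p_op} {self.p}"


def parse_apa(s: str) -> ReportedTest:
    """Parse an APA-style statistic string.

    Grammar: ``F(a,b) = x`` or ``F[a,b] = x`` or ``t(df) = x``, optionally
    followed by ``, p = v`` / ``; p < v`` / ``, p > v``.  Whitespace-tolerant;
    p values may be written ``.04``.
    """
    m = _APA_RE.match(s)
    if m is None:
        token = s.strip().split()[0] if s.strip() else "<empty>"
        raise ParseError(f"cannot parse statistic string starting at {token!r}: {s!r}")
    family = "F" if m.group("family") == "F" else "t"
    df1 = int(m.group("df1"))
    df2_text = m.group("df2")
    if family == "F":
        if df2_text is None:
            raise ParseError(f"F statistic needs two degrees of freedom: {s!r}")
        df2 = int(df2_text)
    else:
        if df2_text is not None:
            raise ParseError(f"t statistic takes a single degrees-of-freedom value: {s!r}")
        df1, df2 = 1, df1
    p_text = m.group("p")
    return ReportedTest(
        family=family,
        statistic=Decimal(m.group("stat")),
        df1=df1,
        df2=df2,
        p=Decimal(p_text) if p_text is not None else None,
        p_op=m.group("op") or "=",
    )


# ---------------------------------------------------------------------------
# fixture IO


def _parse_row(record: dict, lineno: int) -> FixtureRow:
    def text(key: str) -> str:
        return (record.get(key) or "").strip()

    n_text = text("n")
    try:
        n = int(n_text) if n_text else None
    except ValueError:
        raise InvalidInputError(f"line {lineno}: n must be an integer, got {n_text!r}")
    prec_text = text("precision")
    try:
        precision = Decimal(prec_text) if prec_text else None
    except InvalidOperation:
        raise InvalidInputError(f"line {lineno}: bad precision {prec_text!r}")
    checks_text = text("checks") or "grim"
    checks = tuple(c.strip() for c in checks_text.split(";") if c.strip())
    unknown = [c for c in checks if c not in _KNOWN_CHECKS]
    if unknown:
        raise InvalidInputError(f"line {lineno}: unknown checks {unknown}")
    for key in ("mean", "sd"):
        value = text(key)
        if value:
            try:
                Decimal(value)
            except InvalidOperation:
                raise InvalidInputError(f"line {lineno}: bad decimal {key}={value!r}")
    return FixtureRow(
        article=text("article"), table=text("table"),
        row_label=text("row_label"), group_label=text("group_label"),
        n=n, mean=text("mean") or None, sd=text("sd") or None,
        precision=precision, checks=checks,
    )


def load_fixtures(path, fmt: str | None = None) -> FixtureSet:
    """Load fixture rows from a CSV or JSON file.

    A malformed file (wrong header, invalid JSON) raises :class:`ParseError`
    with the offending line; rows that violate the schema are collected into
    ``FixtureSet.errors`` and the rest of the file is still loaded.
    """
    path = str(path)
    if fmt is None:
        fmt = "json" if path.endswith(".json") else "csv"
    rows: list[FixtureRow] = []
    errors: list[str] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != CSV_HEADER:
                raise ParseError(
                    f"{path}:1: header must be exactly {','.join(CSV_HEADER)}"
                )
            for lineno, record in enumerate(reader, start=2):
                try:
                    rows.append(_parse_row(record, lineno))
                except InvalidInputError as exc:
                    errors.append(str(exc))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{exc.lineno}: {exc.msg}") from exc
        if not isinstance(data, list):
            raise ParseError(f"{path}: JSON fixture must be a list of row objects")
        for i, record in enumerate(data):
            try:
                record = {k: "" if v is None else str(v) for k, v in record.items()}
                rows.append(_parse_row(record, i))
            except InvalidInputError as exc:
                errors.append(str(exc))
    else:
        raise InvalidInputError(f"unknown fixture format {fmt!r}")
    return FixtureSet(rows=rows, errors=errors)


def dump_fixtures(rows: Iterable[FixtureRow], path) -> None:
    """Write fixture rows as schema CSV (decimals stay text)."""
    with open(str(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in rows:
            writer.writerow([
                r.article, r.table, r.row_label, r.group_label,
                "" if r.n is None else r.n, r.mean or "", r.sd or "",
                "" if r.precision is None else str(r.precision),
                ";".join(r.checks),
            ])


# ---------------------------------------------------------------------------
# audit


@dataclass(frozen=True)
class AuditConfig:
    """Options applied to every row of an audit run."""

    item_range: tuple[int, int] | None = None
    population_sd: bool = False
    percent_precision: Decimal = Decimal("0.1")


@dataclass
class AuditReport:
    findings: list[Finding]
    errors: list[str] = field(default_factory=list)

    @property
    def by_severity(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.findings:
            out[f.severity] = out.get(f.severity, 0) + 1
        return out

    @property
    def by_check(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.findings:
            out[f.check] = out.get(f.check, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "findings": [f.to_dict() for f in self.findings],
            "errors": list(self.errors),
            "summary": {"by_severity": self.by_severity, "by_check": self.by_check},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AuditReport":
        return cls(
            findings=[Finding.from_dict(f) for f in d["findings"]],
            errors=list(d.get("errors", [])),
        )


def _sort_key(row: FixtureRow):
    return (row.article, row.table, row.row_label, row.group_label)


def run_audit(rows: Sequence[FixtureRow], config: AuditConfig | None = None) -> AuditReport:
    """Apply each row's requested checks and aggregate the findings.

    grim/grimmer run per row.  The f/t checks collect the rows sharing an
    (article, table, row_label) into groups and report the recomputed one-way
    statistic with its rounding bounds as an informational finding (the row
    schema carries no reported statistic to compare against).
    Ordering is deterministic: findings follow (article, table, row, group).
    """
    config = config or AuditConfig()
    findings: list[Finding] = []
    errors: list[str] = []
    ordered = sorted(rows, key=_sort_key)

    for row in ordered:
        try:
            findings.extend(_row_findings(row, config))
        except InvalidInputError as exc:
            errors.append(f"{row.location}: {exc}")

    # grouped t/F recomputation
    groups: dict[tuple[str, str, str], list[FixtureRow]] = {}
    for row in ordered:
        if "f" in row.checks or "t" in row.checks:
            groups.setdefault((row.article, row.table, row.row_label), []).append(row)
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            errors.append(
                f"{members[0].location}: f/t checks need at least two groups per row label"
            )
            continue
        try:
            findings.append(_group_finding(members))
        except InvalidInputError as exc:
            errors.append(f"{members[0].location}: {exc}")
    return AuditReport(findings=findings, errors=errors)


def _row_findings(row: FixtureRow, config: AuditConfig) -> list[Finding]:
    out = []
    if "grim" in row.checks and row.mean is not None:
        if row.n is None:
            raise InvalidInputError("grim check needs n")
        rm = ReportedMean(row.mean_value(), row.n)
        verdict = grim_check(rm)
        out.append(Finding(
            check="grim",
            location=row.location,
            reported=row.mean,
            recomputed=(
                "achievable" if verdict.consistent else
                f"nearest achievable {verdict.nearest_below} / {verdict.nearest_above}"
            ),
            severity="consistent" if verdict.consistent else "inconsistent",
            message=verdict.detail or f"mean {row.mean} at n={row.n} is achievable",
        ))
    if "grimmer" in row.checks and row.sd is not None:
        if row.n is None:
            raise InvalidInputError("grimmer check needs n")
        mean = row.mean_value()
        rs = ReportedSD(
            row.sd_value(), row.n,
            mean=ReportedMean(mean, row.n) if mean is not None else None,
            item_range=config.item_range,
        )
        verdict = grimmer_check(rs, population_sd=config.population_sd)
        out.append(Finding(
            check="grimmer",
            location=row.location,
            reported=row.sd,
            recomputed=(
                f"witness (sum, sum of squares) = {verdict.witnesses[0]}"
                if verdict.consistent else
                f"nearest achievable {verdict.nearest_below} / {verdict.nearest_above}"
            ),
            severity="consistent" if verdict.consistent else "inconsistent",
            message=verdict.detail or f"sd {row.sd} at n={row.n} is achievable",
        ))
    return out


def _group_finding(members: list[FixtureRow]) -> Finding:
    groups = []
    for row in members:
        if row.n is None or row.mean is None or row.sd is None:
            raise InvalidInputError("f/t checks need n, mean and sd for every group")
        groups.append(GroupSummary(
            row.group_label or row.location, row.n, row.mean_value(), row.sd_value()
        ))
    want_t = len(groups) == 2 and all("t" in r.checks for r in members)
    rt: RecomputedTest = pooled_t(groups[0], groups[1]) if want_t else oneway_f(groups)
    bounds = stat_bounds(groups, selector="t" if want_t else "F")
    first = members[0]
    location = " / ".join(p for p in (first.article, first.table, first.row_label) if p)
    return Finding(
        check="t_recompute" if want_t else "f_recompute",
        location=location,
        reported="-",
        recomputed=f"{rt.family}({rt.df1},{rt.df2}) = {rt.statistic:.4f}, p = {rt.p:.4f}",
        severity="consistent",
        message=(
            f"recomputed {rt.family} = {rt.statistic:.4f} "
            f"(possible range [{bounds.lower:.4f}, {bounds.upper:.4f}] at +/-"
            f"{bounds.perturbation}); compare against the published statistic"
        ),
    )


# ---------------------------------------------------------------------------
# rendering


def render(report: AuditReport, fmt: str = "json") -> str:
    """Render an audit report as json, markdown or tsv (deterministic)."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if fmt == "tsv":
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(["check", "location", "reported", "recomputed", "severity", "message"])
        for f in report.findings:
            writer.writerow([f.check, f.location, f.reported, f.recomputed, f.severity, f.message])
        return buf.getvalue()
    if fmt == "markdown":
        lines = [
            "| check | location | reported | recomputed | severity |",
            "| --- | --- | --- | --- | --- |",
        ]
        for f in report.findings:
            lines.append(
                f"| {f.check} | {f.location} | {f.reported} | {f.recomputed} | {f.severity} |"
            )
        counts = report.by_severity
        lines.append("")
        lines.append(
            "Summary: "
            + ", ".join(f"{k}: {counts[k]}" for k in sorted(counts))
            + (f"; {len(report.errors)} row error(s)" if report.errors else "")
        )
        return "\n".join(lines) + "\n"
    raise InvalidInputError(f"unknown render format {fmt!r}")
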