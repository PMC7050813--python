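# statforensics

Consistency checks for published summary statistics — for readers, reviewers
and editors who want to verify reported results *without* access to the raw
data.

When a study reports integer-valued responses (Likert items, counts,
percentages of a sample), its printed statistics are **granular**: a mean of
*n* integers is a multiple of 1/*n*, and at *n* < 100 that spacing is coarser
than the two decimals usually printed. Published test statistics, degrees of
freedom and sample sizes are similarly over-determined: each can be recomputed
from the others. This package implements those audits:

- **GRIM** — is a printed mean `x̄` achievable as `S/n` for any integer total
  `S`, given the inclusive rounding interval `[x̄ − p/2, x̄ + p/2]` of the
  printed precision `p`? Percentages and multi-item composite means are
  handled via a multiplier and an item count.
- **GRIMMER** — is a printed sample SD achievable, i.e. do an integer sum `S`
  and sum of squares `Q` exist with `S/n` in the mean's interval,
  `√((nQ − S²)/(n(n−1)))` in the SD's interval, and a genuine multiset of `n`
  integers (optionally bounded to the response scale) realising `(S, Q)`?
  Feasibility is decided exactly, so verdicts agree with exhaustive
  enumeration.
- **t/F reconstruction** — one-way and two-way between-subjects ANOVA (and the
  pooled t, with `t² = F` for two groups) recomputed from per-cell `n, m, s`;
  plus conservative bounds obtained by perturbing every mean by ±0.005 (all
  `2^cells` combinations) and shifting all SDs down/up, so that a reported
  statistic outside `[F_min, F_max]` is provably inconsistent with its own
  table.
- **p recomputation** — upper-tail p values from the reported statistic and
  DFs, compared with the printed p (equality at printed precision, or an
  inequality such as `p < .01`), including APA-string parsing
  (`"F[1,122] = 4.24; P = 0.04"`).
- **DF audits** — the total sample size implied by reported DFs under a stated
  design (one-way: `N = df2 + k`; factorial: `N = df2 + ab`; repeated
  measures: `n = df2/df1 + 1`; regression: `N = df2 + df1 + 1`), with
  "impossible" reserved for implied `N` *greater* than the stated sample.
- **Count bookkeeping** — exact counts from cumulative "at least k" counts,
  subgroup-sum checks, subset-versus-superset comparisons, the pigeonhole
  bound `⌈total/parts⌉`, cell-by-cell table comparison, and rounded
  unit-conversion intervals.
- **Synthetic data & oracles** — a seeded integer-data generator plus
  brute-force enumeration and raw-data ANOVA, so every check is validated
  against ground truth in the test suite.

All granularity arithmetic is exact (decimal/rational); printed values are
carried as text because `"1.20"` and `"1.2"` are different claims.

## Worked example

A table reports two groups of 10 diners with means 2.00 / 3.00 and SDs
1.00 / 1.00, and elsewhere the text claims `F[1,122] = 4.24; P = 0.04` for a
sample of 122:

```python
from statforensics import (GroupSummary, oneway_f, stat_bounds, bounds_verdict,
                           DesignSpec, ReportedDF, df_verdict)

g1 = GroupSummary.make("$4", 10, "2.00", "1.00")
g2 = GroupSummary.make("$8", 10, "3.00", "1.00")
print(oneway_f([g1, g2]))            # F(1,18) = 5.0000, p = 0.0382
b = stat_bounds([g1, g2], "F")       # possible F range [4.8519, 5.1519]
print(bounds_verdict("5.10", b).severity)   # consistent
print(bounds_verdict("6.00", b).severity)   # inconsistent

f = df_verdict(ReportedDF(1, 122), DesignSpec("oneway_between", 2), stated_n=122)
print(f.severity)   # impossible — F(1,122) needs 124 participants, only 122 exist
```

The `examples/` directory holds one short script per capability; for instance
`python examples/grim_granularity.py` prints

```
mean 4.26 at n=58: consistent
mean 4.27 at n=58: IMPOSSIBLE
mean 4.28 at n=58: consistent
```

meaning that at n = 58 the printed value 4.27 cannot be the rounded mean of
any 58 integers, while a one-digit misprint of 4.28 as 4.26 would evade the
test — granularity checks have false negatives, never false positives.

`examples/fixtures/appendix_granularity.csv` transcribes 54 flagged means/SDs
from four related consumer-behaviour articles; `python examples/audit_fixture.py`
re-audits them (42/42 transcribed means are impossible at their stated
sample sizes).

A thin CLI mirrors the library for one-off checks:

```
statforensics grim --mean 6.62 --n 62
statforensics df --design oneway --k 3 --df 2,84 --n 95
statforensics audit examples/fixtures/appendix_granularity.csv --format markdown
```

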