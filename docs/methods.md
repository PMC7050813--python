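# Methods

This note records the statistical conventions, algorithms and design choices
behind `statforensics`, and what its tests do and do not demonstrate.

## Rounding model

Every printed decimal is treated as an *inclusive* half-interval: a value `v`
at precision `p` stands for any true value in `[v − p/2, v + p/2]`, with both
endpoints allowed because a quantity landing exactly on a rounding boundary
may be rounded either way by common software. This is the conservative
choice throughout: it can only reduce the number of values flagged, never
create a spurious flag. Interval arithmetic uses exact base-10 types
(`Decimal` for printed values, `Fraction` for derived quantities); binary
floats never decide interval membership, so representational boundaries
(e.g. 0.125) cannot produce artefacts. Printed precision is inferred from
the text — `"2.30"` claims two decimals, `"2.3"` one — which is why fixture
files carry decimals as strings.

The synthetic-data generator's `summarize` rounds half-away-from-zero, the
behaviour of most statistics packages when printing; the inclusive interval
accepts either midpoint direction, so any consistent rounding rule on the
data side is covered.

## GRIM

A mean of `n` integer responses, averaged over `items` scale items and
scaled by `multiplier` (1 for raw means, 100 for percentages), is consistent
iff an integer total `S` exists with `S/(n·items)·multiplier` inside the
printed mean's interval. This reduces to checking whether
`⌈lo·n·items/multiplier⌉ ≤ ⌊hi·n·items/multiplier⌋`, which is exact and O(1).
Inconsistent verdicts also report the nearest achievable printed values on
either side, found by walking the printed grid outward (the achievable values
are at most `multiplier/(n·items)` apart, which bounds the walk).

Continuous measurements (age, height, weight) are out of scope: granularity
testing requires knowing the data are integers, and for such variables the
collection procedure is usually unstated.

## GRIMMER

A printed sample SD is consistent iff integers `(S, Q)` exist such that

1. `S/n` lies in the mean's interval (when a mean is reported) — a mean that
   already fails GRIM therefore forces an inconsistent SD verdict;
2. `Q ≡ S (mod 2)` — the sum and sum of squares of integers share parity;
3. `(nQ − S²)/(n(n−1))` lies in `[sd_lo², sd_hi²]` (denominator `n` instead
   of `n − 1` with `population_sd=True`; sample SDs are the default
   assumption);
4. a multiset of `n` integers with sum `S` and sum of squares `Q` exists,
   within the response-scale bounds when they are known.

Conditions 1–3 narrow the search to a handful of `(S, Q)` candidates, since
the SD interval maps to a `Q` window of width `≈ 2(n−1)·sd·p`. Condition 4
is decided **exactly** by a depth-first search over value counts, pruned by
the minimum sum of squares (near-equal partition of `S`) and the maximum
(all mass at the extremes). The pruning bounds alone — parity plus min/max —
are *not* a decision procedure: for example `n = 2, S = 6, Q = 22` passes
them, yet no integer pair attains it (`{3,3} → 18, {2,4} → 20, {1,5} → 26`).
Treating them as exact would produce false "consistent" verdicts precisely in
the small-`n` regime where granularity testing matters, so the search runs to
completion; the test suite verifies agreement with exhaustive multiset
enumeration for every `n ≤ 12` on a 1–7 scale. When no response-scale bounds
are given, a finite search domain follows from the fact that every value lies
within `√(Q − S²/n)` of the mean; when no mean is reported either, integer
sums are searched over the documented default window `|S/n| ≤ 10·(sd + 1)`
(overridable by supplying an item range). Consistent verdicts return the
`(S, Q)` witness.

GRIMMER is restricted to raw means (`items = 1`, `multiplier = 1`): the
sum-of-squares granularity of multi-item composites depends on the per-item
joint distribution and is not well defined from the printed summary alone.

## t/F reconstruction

One-way `F` uses the standard decomposition from summaries: between mean
square `Σ nᵢ(mᵢ − m̄)²/(k−1)` about the `n`-weighted grand mean, within mean
square `Σ (nᵢ−1)sᵢ²/(N−k)`. The pooled two-sample `t` satisfies `t² = F`
identically. Degenerate inputs are verdicts, not exceptions: all variances
zero with equal means gives `F = 0, p = 1`; with unequal means the statistic
is unbounded and is returned as `inf` with `p = 0` and an `overflow` flag.

Two-way between-subjects ANOVA defaults to the **unweighted-means** analysis:
effect sums of squares computed from equally weighted cell means, scaled by
the harmonic mean of the cell sizes, with the error term pooled within cells
and DFs `(a−1)`, `(b−1)`, `(a−1)(b−1)` over `N − ab`. This matches the
summary-statistics ANOVA lineage most reconstruction tools implement and
coincides with the textbook analysis for balanced designs (verified against
`statsmodels` on raw data). Because published tables rarely say which
sums-of-squares decomposition produced them, a size-weighted variant is
available via `method="weighted"`.

Repeated-measures statistics are *not* reconstructed: they require the
within-subject correlations, which summary tables never report. Only their
DF audit is supported. Welch/unequal-variance t is likewise out of scope —
pooled-variance tests are what the audited style of table implies.

### Rounding-perturbation bounds

For a statistic reconstructed from two-decimal summaries, the upper bound
subtracts the half-step (default 0.005) from every SD and takes the maximum
over all `2^cells` assignments of ±half-step to the means; the lower bound
adds the half-step to every SD and takes the minimum over the same mean
assignments. Mean perturbations must be enumerated because the statistic is
not monotone in any one mean; the SD shift is applied monotonically because
`F` is decreasing in each SD, so the extremes are attained at the common
shift — the enumeration over SD signs would be redundant, not more accurate.
SDs are floored at zero after downward perturbation (a negative SD is
meaningless, and the floor only widens the interval, i.e. stays
conservative). Enumeration is refused above 20 cells (2²⁰ evaluations).
With perturbation 0 the bounds collapse to the exact reconstruction. A
reported statistic is accepted when its own printed interval intersects
`[lower, upper]` — again the conservative direction. The containment
guarantee (the raw-data statistic always lies inside the bounds of its
rounded summaries) is exercised over 1,000 seeded datasets in the tests.

### p values

Recomputed p values are upper-tail probabilities from the F distribution (or
two-tailed t by default, one-tailed by flag). A reported `p = v` is accepted
when the recomputed p can round to `v` at the precision `v` is printed with
(inclusive endpoints); `p < v` / `p > v` are accepted when the recomputed p
satisfies the inequality strictly.

## DF audits

Implied sample sizes: one-way `N = df2 + k`; factorial `N = df2 + a·b` (df1
is validated against the candidate effects `(a−1)`, `(b−1)`, `(a−1)(b−1)`);
repeated measures `n = df2/df1 + 1`, with non-integral results reported as
inconsistencies; regression `N = df2 + df1 + 1` with an intercept. An
implied `N` larger than the stated sample is *impossible* (no analysis has
more error DF than cases); a smaller implied `N` is only a soft
inconsistency, because software silently drops incomplete cases (listwise
deletion). For regressions the verdict message also notes when the
discrepancy would vanish under the no-intercept DF convention, since
articles are rarely explicit about the intercept.

## Count bookkeeping

Cumulative "at least k" counts difference to exact counts
(`exact[i] = at_least[i] − at_least[i+1]`, last bin passed through); an
increasing cumulative sequence yields a negative exact count and is reported
as an impossible finding rather than raising, because that is itself the
interesting result. Cross-table comparison uses exact decimal equality by
default — two renderings of the same table have no legitimate reason to
differ — with tolerance opt-in. Unit conversions map the source value's
interval through the factor (defaults 2.2046226218 lb/kg, 0.3937007874
in/cm, both overridable since the factor an article used is unknown; re-run
with 2.2 to probe sensitivity).

## Synthetic data

`generate(seed, ...)` draws integer responses by rounding and clipping a
normal distribution centred on the scale midpoint (spread: a quarter of the
scale width by default), one explicit-seed PRNG per call and no global
state. This emulates the *reporting structure* of small-sample Likert-type
tables — integer data, per-group n/mean/SD, two-decimal printing — which is
all the audits consume. It does not emulate any behavioural content
(condition effects on real diners, response dependence, missingness), so
passing tests certify the arithmetic of the checks, not any substantive
claim about restaurant field data. Oracles are deliberately independent
routes: multiset enumeration (order-free, shrinking the space from `kⁿ` to
`C(n+k−1, n)`, guarded at 5·10⁶ multisets) for granularity, and raw-value
sums of squares (cross-checked against `scipy.stats.f_oneway` and
`statsmodels` in the tests) for ANOVA.

Problem sizes used by the test suite and kept fixed: GRIM verdicts are
compared with sum enumeration for every two-decimal mean in [1, 9] at every
`n ≤ 200`; GRIMMER against full multiset enumeration for `n ≤ 12` on a 1–7
scale (achievable pairs plus all one-step neighbours); reconstruction and
containment over 1,000 seeded datasets of 3×20 observations; soundness
(no false positives on honestly rounded summaries) over 300 seeded datasets
of varying shape.

## The fixture row schema

Fixture rows carry `(article, table, row_label, group_label, n, mean, sd,
precision, checks)`. The `grim`/`grimmer` checks run per row; the `f`/`t`
checks pool the rows sharing `(article, table, row_label)` and report the
recomputed statistic with its rounding bounds as an informational finding —
the schema has no column for a published statistic to compare against, so
that comparison is done via `bounds_verdict`/the CLI where the reported value
is at hand. DF audits likewise take their inputs (design, DF pair, stated N)
directly rather than through fixture rows.

The shipped `examples/fixtures/appendix_granularity.csv` transcribes flagged
means and SDs exactly as printed in the source audit's appendix. Rows with
an SD but no printed mean run GRIMMER mean-free, which is strictly weaker —
several such SDs are achievable for *some* mean and correctly come back
consistent; with the (unpublished) table mean supplied they could still be
impossible. Percentage entries are not representable in the fixed row schema
(no multiplier column) and are exercised through the API instead.

## Known limitations

- Granularity tests have false negatives by construction: a wrong value that
  happens to be achievable (e.g. 4.26 for a true 4.28 at n = 58) passes.
- GRIMMER without a mean or response-scale bounds searches a finite default
  window and is weak, as noted above.
- The two-way reconstruction cannot know which decomposition an article used
  for unbalanced data; both offered variants are between-subjects only.
- The DF audit covers the four standard designs; mixed models, ANCOVA and
  Welch-corrected fractional DFs are out of scope.
- APA parsing covers single `F(...)`/`t(...)` statistic strings, not document
  mining.
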