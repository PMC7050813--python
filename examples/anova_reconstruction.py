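"""Recompute a t/F statistic from per-group summaries, with rounding bounds.

Published means and SDs are rounded, so the reconstructed statistic is not a
point but an interval: the bounds perturb every mean by +/-0.005 (all
combinations) and shift all SDs down (upper bound) or up (lower bound).
A reported statistic whose own rounding interval misses that interval cannot
have come from the reported summaries.
"""

from statforensics import (
    GroupSummary,
    bounds_verdict,
    oneway_f,
    p_agreement,
    parse_apa,
    pooled_t,
    stat_bounds,
)

g1 = GroupSummary.make("$4 buffet", 10, "2.00", "1.00")
g2 = GroupSummary.make("$8 buffet", 10, "3.00", "1.00")

f = oneway_f([g1, g2])
t = pooled_t(g1, g2)
print(f"reconstructed F({f.df1},{f.df2}) = {f.statistic:.4f}, p = {f.p:.4f}")
print(f"equivalently t({t.df2}) = {t.statistic:.4f}  (t^2 = {t.statistic**2:.4f} = F)")

bounds = stat_bounds([g1, g2], "F")
print(f"possible F range given rounding: [{bounds.lower:.4f}, {bounds.upper:.4f}]")

for reported in ("5.10", "6.00"):
    verdict = bounds_verdict(reported, bounds)
    print(f"reported F = {reported}: {verdict.severity}")

# checking a p value against a statistic transcribed from an article
parsed = parse_apa("F[1,122] = 4.24; P = 0.04")
from scipy import stats

p = float(stats.f.sf(float(parsed.statistic), parsed.df1, parsed.df2))
from statforensics import RecomputedTest

finding = p_agreement(
    RecomputedTest("F", float(parsed.statistic), parsed.df1, parsed.df2, p=p),
    (parsed.p_op, parsed.p),
)
print(f"F(1,122) = 4.24 gives p = {p:.4f}; reported p = 0.04 is {finding.severity}")
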