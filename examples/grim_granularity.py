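"""GRIM: which printed means are possible for integer data at a given n?

A mean of 58 integer responses can only be a multiple of 1/58, so most
two-decimal values are unreachable.  The check below shows that 4.27 is
impossible at n=58 while its neighbours 4.26 and 4.28 are fine — which is
exactly why a one-digit typo can slip past the test.
"""

from decimal import Decimal

from statforensics import ReportedMean, RoundedValue, grim_check, grim_reachable

for text in ("4.26", "4.27", "4.28"):
    verdict = grim_check(ReportedMean(RoundedValue.from_text(text), 58))
    status = "consistent" if verdict.consistent else "IMPOSSIBLE"
    print(f"mean {text} at n=58: {status}")

print()
reachable = grim_reachable(58, (Decimal("4.20"), Decimal("4.35")))
print("every printed value reachable in [4.20, 4.35] at n=58:")
print("  " + ", ".join(str(v) for v in reachable))

# percentages have granularity 100/n: 57.4% of 62 people is impossible
pct = grim_check(ReportedMean(RoundedValue.from_text("57.4"), 62, multiplier=100))
print()
print(f"57.4% of n=62: {'consistent' if pct.consistent else 'IMPOSSIBLE'} "
      f"(nearest achievable: {pct.nearest_below}%, {pct.nearest_above}%)")
# An impossible value means no count of 62 people rounds to the printed percentage.
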