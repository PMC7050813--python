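"""GRIMMER: is a printed SD reachable by any integer dataset?

The check searches for an integer sum S and sum of squares Q that reproduce
both the printed mean and the printed SD at the stated n.  A consistent
verdict comes with a (S, Q) witness; an inconsistent one brackets the
reported SD with the nearest achievable printed values.
"""

from statforensics import ReportedMean, ReportedSD, RoundedValue, grimmer_check


def check(mean_text, sd_text, n, item_range=None):
    rs = ReportedSD(
        RoundedValue.from_text(sd_text), n,
        mean=ReportedMean(RoundedValue.from_text(mean_text), n),
        item_range=item_range,
    )
    v = grimmer_check(rs)
    if v.consistent:
        s, q = v.witnesses[0]
        print(f"mean {mean_text}, sd {sd_text}, n={n}: consistent "
              f"(witness: sum={s}, sum of squares={q})")
    elif v.nearest_below is None and v.nearest_above is None:
        print(f"mean {mean_text}, sd {sd_text}, n={n}: IMPOSSIBLE ({v.detail})")
    else:
        print(f"mean {mean_text}, sd {sd_text}, n={n}: IMPOSSIBLE "
              f"(nearest achievable SDs: {v.nearest_below}, {v.nearest_above})")


# a published pair that no ten integers can produce (the mean already fails GRIM)
check("1.18", "0.40", 10)
# the classic 1..5 dataset on a 5-point scale: sd sqrt(2.5) prints as 1.58
check("3.00", "1.58", 5, item_range=(1, 5))
# ten identical answers: zero variance is always fine
check("2.00", "0.00", 10)
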