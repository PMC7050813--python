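"""Sample-size bookkeeping: DFs, cumulative counts, sums and subsets.

Reported degrees of freedom pin down the sample size a test was run on;
cumulative "at least k" counts difference into exact counts; subgroup counts
must add up; a subsample can never out-count its parent sample.  Each check
below uses numbers of the kind found in the audited articles.
"""

from statforensics import (
    CumulativeCounts,
    DesignSpec,
    ReportedDF,
    df_verdict,
    exact_from_cumulative,
    partition_min_max,
    subset_check,
    sum_check,
)

# A one-way ANOVA over 3 groups reported F(2, 84): that needs N = 87,
# yet the article states 95 diners.
finding = df_verdict(ReportedDF(2, 84), DesignSpec("oneway_between", 3), stated_n=95)
print(f"{finding.severity}: {finding.message}")

# F(1,122) from a 2-group comparison implies 124 participants out of 122.
finding = df_verdict(ReportedDF(1, 122), DesignSpec("oneway_between", 2), stated_n=122)
print(f"{finding.severity}: {finding.message}")

# regression-model Ns are cumulative: >=1 slice, >=2 slices, >=3 slices
result = exact_from_cumulative(CumulativeCounts((1, 2, 3), (62, 47, 41)))
print(f"cumulative (62, 47, 41) -> exactly 1: {result.exact[0]}, "
      f"exactly 2: {result.exact[1]}, at least 3: {result.exact[2]}")

# the six condition counts should add to the stated 95 diners
finding = sum_check((18, 18, 7, 17, 19, 10), 95)
print(f"{finding.severity}: {finding.message}")

# a filtered re-analysis of the same diners cannot have larger groups
labels = ("1 piece/$4", "1 piece/$8", "2 pieces/$4", "2 pieces/$8")
parent = dict(zip(labels, (15, 22, 6, 12)))
subset = dict(zip(labels, (18, 19, 18, 21)))
violations = subset_check(subset, parent)
print(f"{len(violations)} of {len(labels)} subset groups exceed their parent group")

# 85 diners split over 1-slice and 2-slice groups: one group holds >= 43,
# so neither can be smaller than the claimed 3-slice mode of 37
print(f"splitting 85 into 2 groups forces a maximum of at least "
      f"{partition_min_max(85, 2)}")
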