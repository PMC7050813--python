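"""Batch audit: run every requested check over a fixture of transcribed values.

The shipped fixture transcribes the flagged means and SDs from four related
consumer-behaviour articles (integer Likert-type responses, two-decimal
reporting).  Every transcribed mean fails GRIM at its stated sample size;
SD-only rows are checked with GRIMMER, which is weaker without the mean.
"""

from pathlib import Path

from statforensics import load_fixtures, render, run_audit

fixture = Path(__file__).parent / "fixtures" / "appendix_granularity.csv"
fixtures = load_fixtures(fixture)
print(f"loaded {len(fixtures.rows)} transcribed statistics")

report = run_audit(fixtures.rows)
counts = report.by_severity
print(f"verdicts: {counts.get('inconsistent', 0)} inconsistent, "
      f"{counts.get('consistent', 0)} consistent")
print(f"per check: {report.by_check}")

# the full report renders deterministically as json / markdown / tsv
markdown = render(report, "markdown")
print()
print("\n".join(markdown.splitlines()[:6]))
print("...")
print(markdown.splitlines()[-1])
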