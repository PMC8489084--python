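"""Reproduce the bundled three-exposure MR analysis end to end.

Loads the packaged instrument sets for serum 25-hydroxyvitamin D, calcium
and parathyroid hormone versus coronary artery disease in diabetes, runs
every estimator and diagnostic, and prints the summary report.  The IVW
odds ratios are per SD of exposure; none reaches the Bonferroni-corrected
significance threshold of 0.05/3, i.e. the data provide no evidence of a
causal effect of any of the three exposures.
"""

from pathlib import Path

from tsmr import run_published_analysis, write_report

report = run_published_analysis(seed=1, n_boot=1000, n_sim=1000)
out_dir = Path("mr_report")
write_report(report, out_dir)

print((out_dir / "summary.txt").read_text())
print(f"Full TSV tables written to {out_dir}/")
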