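"""Summarize the packaged published benchmark of tuned vs default AUPRC.

The packaged table records scDblFinder's AUPRC on 16 annotated scRNA-seq
datasets under the tuned optimum, the method defaults, and the best of the
125 design points.
"""

import dbltune as dt

tables = dt.load_benchmark_tables()
report = dt.report_from_fixtures(tables)

print(report.per_dataset.round(3).to_string(index=False))
print()
print(f"datasets where tuning beats the defaults: {report.n_outperforming} of 16")
print(f"largest relative improvement: {report.max_improvement_pct:.3f}% "
      f"on {report.max_improvement_dataset}")
# Negative rows (e.g. the species-mixture datasets hm-6k / hm-12k) are the
# cases where the globally tuned optimum loses to the defaults.
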