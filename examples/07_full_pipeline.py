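"""Run the whole pipeline end to end and read the summary.

Equivalent to `methcrossover run-all --outdir out/`; every stage report
is written as TSV and the headline numbers land in summary.json.
"""

import json
import tempfile
from pathlib import Path

from methcrossover import run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="methcrossover_"))
summary = run_pipeline({"seed": 1}, outdir)

print(f"reports written to {outdir}:")
for p in sorted(outdir.iterdir()):
    print(f"  {p.name}")

print("\nheadlines:")
print(f"  obesity DMCs: {summary['n_dmc_obesity']}, CRC DMCs: {summary['n_dmc_crc']}")
dmc = summary["dmc_overlap"]
print(
    f"  overlapping DMCs: {dmc['n_overlap']} "
    f"({dmc['pct_of_obesity']:.0f}% of obesity DMCs), "
    f"concordant {100 * dmc['concordant_fraction']:.0f}%, chi2 p = {dmc['chi2_p']:.2g}"
)
dmr = summary["dmr_overlap"]
print(f"  overlapping DMRs: {dmr['n_overlap']}, selected after rank tests: {summary['n_selected']}")
print(f"  expression concordance: {summary['expression_concordance']}")
print("\nfull summary:")
print(json.dumps(summary, indent=2, sort_keys=True)[:600], "...")
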