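"""Generate the three-population synthetic cohort and write it to disk.

The shipped presets emulate 291 VTA neurons: 22 high-firing (putatively
GABAergic) pacemakers, 205 low-firing/low-bursting and 64 low-firing/
high-bursting putative dopaminergic neurons.
"""

import sys

from vtaclust import write_cohort
from vtaclust.synthetic import generate_population, ground_truth_frame, paper_presets

out = sys.argv[1] if len(sys.argv) > 1 else "cohort_out"
cohort = generate_population(paper_presets(), seed=0)
truth = ground_truth_frame(cohort)
write_cohort([n.session for n in cohort], out, extra_columns=truth)

by = truth.groupby("true_label")
print(f"wrote {len(cohort)} recordings (+ index.csv with ground truth) to {out}/")
print()
print(by.agg(n=("true_rate_hz", "size"),
             rate_hz=("true_rate_hz", "mean"),
             pct_sib=("true_pct_sib", "mean"),
             ap_ms=("true_ap_ms", "mean"),
             dt1_ms=("true_dt1_ms", "mean")).round(2))
print()
print("Group means match the population targets the presets encode; per-file")
print("formats are plain text (spikes.txt, waveform.csv, meta.json).")
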