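"""Cluster the non-high-firing neurons and score recovery against truth.

Generates the 205+64 putative-DA cohort, extracts features, scales, votes on
the cluster number, cuts the Ward tree, and compares the partition with the
generating populations via the adjusted Rand index.
"""

from sklearn.metrics import adjusted_rand_score

from vtaclust import (
    prefilter_high_firing,
    scale_minmax,
    select_cluster_number,
    ward_cluster,
)
from vtaclust.features import extract_feature_frame
from vtaclust.synthetic import generate_population, ground_truth_frame, paper_presets

presets = [p for p in paper_presets() if p.name != "cluster1"]
cohort = generate_population(presets, seed=0)
feat = extract_feature_frame([n.session for n in cohort])
truth = ground_truth_frame(cohort)

high, rest = prefilter_high_firing(feat)
scaled = scale_minmax(rest)
report = select_cluster_number(scaled)
print(f"index votes: {report.per_index_choice}  ->  selected k = {report.selected_k}")

dend, assignment = ward_cluster(scaled, report.selected_k)
labels = assignment.series()
ari = adjusted_rand_score(truth.loc[labels.index, "true_label"], labels)
print(f"adjusted Rand index vs generating populations: {ari:.3f}")

for c in sorted(labels.unique()):
    part = rest.loc[labels[labels == c].index]
    print(f"cluster {c}: n={len(part):3d}  rate={part['firing_rate_hz'].mean():.2f} Hz"
          f"  %SIB={part['pct_sib'].mean():5.2f}  (range {part['pct_sib'].min():.1f}"
          f"-{part['pct_sib'].max():.1f})")
print()
print("The two clusters separate by burst activity; an ARI near 1 means the")
print("unsupervised cut recovers the generating populations almost exactly.")
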