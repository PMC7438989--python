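# vtaclust

Unsupervised electrophysiological classification of ventral tegmental area
(VTA) neurons recorded in vivo with extracellular single-unit electrodes.

The VTA mixes dopaminergic (DA), GABAergic and glutamatergic neurons whose
conventional identification criteria — firing rate, firing regularity, burst
firing, action-potential (AP) width and shape — overlap heavily between cell
types. `vtaclust` implements an objective alternative: extract six classical
features per neuron, set aside fast-firing units, and let agglomerative
clustering partition the rest. It is aimed at electrophysiologists who want
a reproducible, pharmacology-free sort of single-unit recordings, and it
ships a fully calibrated synthetic-population generator so every stage can
be exercised (and unit-tested) without access to original recordings.

## Method

Per neuron, from spike timestamps and the mean AP waveform:

1. **firing rate** — spikes per second over the recording window;
2. **firing-rate CV** — SD/mean of rates in consecutive 10 s bins
   (regularity index);
3. **%SIB** — percentage of spikes in bursts under the classical
   Grace–Bunney interspike-interval rule: a burst opens when two spikes fall
   within 80 ms, extends while ISIs stay below 160 ms, and must be
   terminated by ≥ 160 ms of silence;
4. **AP duration** — depolarization onset to the final return to baseline;
5. **Δt₁** — onset to the end of repolarization (first baseline re-crossing
   after the trough);
6. **notch** — presence of a secondary inflection (local-extremum pair with
   prominence ≥ 5% of the peak-to-trough amplitude) on the AP's rising or
   falling limb.

Units firing above 10 Hz are pre-filtered as putatively GABAergic. The
remaining feature matrix is min–max scaled to [0, 1] per column, checked by
PCA (SVD) for variance capture, and clustered with Ward's minimum-variance
method on Euclidean distances (the Ward.D2 dialect). The number of clusters
is chosen by a majority vote of four internal validity indices (silhouette,
Calinski–Harabasz, Davies–Bouldin, Dunn), with mean silhouette width
breaking ties. Clusters are characterized with mean ± SEM summaries,
Kruskal–Wallis + Dunn (Bonferroni) tests and chi-square contingency tests.

The synthetic generator builds spike trains from an explicit event process
(bursts vs. single spikes separated by ≥ 170 ms gaps) so the burst detector
recovers the constructed labels *exactly*, and builds AP waveforms from a
biphasic template calibrated against the package's own waveform metrics.
Population presets reproduce the three groups reported for a 291-neuron
in vivo cohort (high-firing; low-firing/low-burst; low-firing/high-burst).

## Worked example

```bash
python examples/run_pipeline.py demo_out
```

prints (seed 0):

```
291 neurons, 22 high-firing excluded by the >10 Hz pre-filter; cluster-number vote selected k = 2
first two principal components carry 80% of the variance

           n  firing_rate_mean  firing_rate_sem  ...  pct_sib_mean  dt1_mean  n_notch
cluster
1         22            18.812            0.804  ...         0.000     0.627        0
2        210             2.032            0.047  ...         3.960     0.994      107
3         59             3.414            0.101  ...        36.588     1.126       33

firing_rate        statistic= 142.724, df=2  p=1.02e-31
pct_sib            statistic= 163.878, df=2  p=2.6e-36
...
notch_contingency  statistic=   0.458, df=1  p=0.499
```

Cluster 1 is the pre-filtered high-firing group (~19 Hz, short APs, no
bursts). The vote selects two clusters among the remaining neurons, which
separate by burst activity (~4% vs ~37% of spikes in bursts) but not by
notch prevalence (chi-square p ≈ 0.5) — firing pattern, not AP shape, is
what distinguishes the putative DA subpopulations. Other entry points:
`examples/extract_features.py` (one neuron), `examples/generate_cohort.py`
(write a cohort to disk), `examples/cluster_cohort.py` (recovery scored
against ground truth), or the `vtaclust` CLI (`generate`, `features`,
`cluster`, `stats`, `run` subcommands).

## Limitations

Input is sorted single-unit data: spike timestamps plus an averaged
waveform. There is no spike sorting, no vendor acquisition formats, no
pharmacological response analysis, and no biophysical simulation. See
`docs/methods.md` for the model details, parameter defaults and the design
rationale behind the synthetic presets.
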