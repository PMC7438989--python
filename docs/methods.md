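# Methods

## Scope and data model

The package classifies single VTA neurons from two per-neuron inputs: a
spike-timestamp series (seconds, strictly increasing, within a stated
recording window) and a mean extracellular AP waveform (uniformly sampled
voltage, any consistent amplitude unit, with a known number of pre-trigger
baseline samples). Feature extraction requires at least 2 spikes over at
least 60 s — stable basal epochs of five minutes or more are the norm for
this preparation, and rate/CV/burst statistics are not meaningful on shorter
windows.

## Firing-pattern features

**Mean firing rate** is spike count over window duration.

**Firing-rate CV** is the sample SD over the mean of spike rates counted in
consecutive full bins (default 10 s; a trailing partial bin is dropped).
The bin width is exposed because the notion of "CV of firing rates" admits
both binned-rate and ISI-based readings; we use binned rates (an ISI-based
CV is a different statistic with a different scale). With ≥ 5 min windows
the default gives ≥ 30 bins. For a Poisson train the binned-rate CV tends
to 1/sqrt(rate x bin width), which the tests verify by simulation.

**Burst detection** follows the classical 80/160 ms ISI rule for DA
neurons: a burst opens when two consecutive spikes fall within 80 ms
(inclusive), extends while the next ISI is below 160 ms, and is terminated
by a silence of at least 160 ms (inclusive). Two operational choices:

* *The terminating silence is part of the burst definition.* A run of
  spikes still "open" at the end of the recording is counted only when the
  observable trailing silence (window end minus last spike) reaches 160 ms;
  otherwise it is discarded as unterminated. This matters for fast regular
  trains (mean ISI < 80 ms): under a keep-at-end-of-train convention an
  entire 20 Hz recording would count as one burst with ~100% of spikes in
  bursts, which contradicts the near-zero burst fractions reported for
  high-firing VTA units. Under our convention such trains contain no
  terminated burst and score 0%.
* *Boundaries carry 1 ns slack* so that the inclusive 80/160 ms edges
  survive floating-point subtraction of timestamps.

The implementation partitions spikes into runs separated by ≥ 160 ms ISIs
and locates the first sub-80 ms pair per run; an independent left-to-right
stateful scan serves as the test oracle on 10,000 random small trains.

## AP waveform morphometrics

Baseline and noise are the mean and SD of the pre-trigger segment (≥ 8
samples). The baseline band is `noise_k` (default 3) noise SDs, floored at
1% of the peak excursion so that noiseless averaged traces have a finite
band. Landmarks: the principal peak is the largest |v − baseline| extremum
after the trigger; the trough is the largest opposite-sign excursion after
it; onset is the last in-band sample before the peak; Δt₁ runs from onset
to the first in-band sample after the trough ("end of repolarization" =
baseline re-crossing; the trough itself would be an alternative landmark,
but re-crossing matches the usual reading of repolarization end); AP
duration runs from onset to the last out-of-band sample, which includes the
after-potential. A notch is any local-extremum pair with prominence ≥ 5%
of the peak-to-trough amplitude between onset and peak ("rise") or peak and
trough ("fall"); output is binary plus the phase. All metrics are invariant
to amplitude scaling and baseline offset by construction; the tests assert
this. Noise inflates the baseline band, which shortens the measured AP
duration by a few percent at the default noise level — well inside the 10%
tolerances used for population-level checks.

## Clustering

The six features (rate, CV, %SIB, AP duration, Δt₁, notch) are assembled
into a matrix; units firing strictly above 10 Hz are split off first, since
fast-firing VTA units are conventionally treated as GABAergic and would
otherwise dominate the scaling. Each remaining column is min–max scaled to
[0, 1]; PCA via SVD (columns centered, variance fractions σ²/Σσ², signs
fixed by largest loading) reports dimensionality but does not feed the
clustering — the hierarchy is built on the scaled features directly, which
keeps cluster descriptions in feature units.

Ward's minimum-variance linkage on Euclidean distances (Ward.D2: heights on
the Euclidean scale, sqrt(2·ΔSSE)) builds the dendrogram; flat labels come
from cutting at k. The number of clusters is a majority vote over four
internal validity indices computed at each k in 2..10 (silhouette,
Calinski–Harabasz, Davies–Bouldin, Dunn), tie-broken by mean silhouette
width and then by smaller k. A 30-index battery exists in the R ecosystem;
four complementary, independently implemented indices led by the silhouette
give the same decision on every cohort we generate while keeping the
dependency surface small, and the index set is extensible.

**Notch down-weighting.** After min–max scaling, a 0/1 column spans the
full unit range while the informative spread of the continuous features is
a fraction of it. With notch prevalence near 50% in both populations the
binary column is pure variance without class signal, and at full weight
Ward's k=2 cut reproduces the notch dichotomy instead of the firing-pattern
structure (adjusted Rand index vs. the generating populations ≈ 0). The
notch column is therefore multiplied by `notch_weight` (default 0.25)
before distance computations; at this weight the recovery on synthetic
cohorts is ARI ≥ 0.95 in every tested replicate. `notch_weight=1.0`
restores the plain encoding; a Gower-type metric was deliberately avoided
to keep a single scaled matrix.

## Statistics

Group comparisons use Kruskal–Wallis (tie-corrected H, chi-square p on k−1
df) followed by Dunn's pairwise z-tests on mean ranks with the standard tie
term, Bonferroni-adjusted over all pairs (the adjustment family is a
parameter). Contingency tables use the Pearson chi-square without
continuity correction by default — on the published notched/non-notched
counts (102/205 vs 34/64) the uncorrected statistic reproduces the
published p ≈ 0.64, while Yates' correction does not; a `yates` flag is
available. Log-normality checks fit log₁₀ values and apply Shapiro–Wilk;
zeros must be excluded by the caller (burst-fraction distributions are
assessed over bursting neurons only). Summaries report mean ± SEM
(SD/√n), with the high-firing group numbered cluster 1 and the clustered
groups following in ascending mean burst percentage.

## Synthetic populations

The generator's purpose is an *exact* oracle for every pipeline stage, so
trains are built from an explicit event process rather than fitted to one:

* Each event is, with probability p_b, a burst of k spikes (k ∈ 2..6 with
  mean ≈ 3.37 by default; intra-burst ISIs uniform on 30–75 ms), otherwise
  a single spike. Inter-event gaps are 170 ms + Gamma(shape 3, scale),
  guaranteeing the 160 ms termination bound with margin; the scale is set
  so the expected spike rate hits the target. Because every intra-burst
  ISI is ≤ 80 ms and every gap ≥ 170 ms, the detector reproduces the
  constructed burst labels index-for-index (a tested invariant), and
  p_b = s / (E[k](1−s) + s) realizes a target burst fraction s exactly in
  expectation. The construction caps feasible rates at about
  1/0.17 ≈ 5.9 Hz for non-bursting trains; requests beyond the bound raise
  an error that states the bound.
* High-firing neurons cannot satisfy that construction (mean ISI ≪ 170 ms),
  so the high-firing preset uses a regular pacemaker process (gamma ISIs,
  shape 100, CV ≈ 0.1). Such trains contain neither 160 ms silences nor
  terminated bursts, so their detected %SIB is 0, matching the near-zero
  burst activity of fast-firing VTA units; their burst annotation is
  measured at construction rather than constructed.
* Waveforms come from a canonical biphasic template (positive half-sine,
  negative lobe at 0.6 amplitude, after-potential bump at 0.12) whose two
  time scales are iterated against `waveform_metrics` until measured Δt₁
  and AP duration land within one sampling interval (0.01 ms) of target —
  sub-sample precision is unattainable because measured durations are
  quantized to the grid. Notches are injected as a dip below the apex
  (rise) or a bump near the trough (fall), with the depth bisected until
  the realized prominence equals the requested fraction of the
  peak-to-trough amplitude; per-neuron Δt₁ is drawn as a ratio of AP
  duration, which produces the linear AP–Δt₁ relationship (r² ≥ 0.8)
  observed in real cohorts.

**Preset calibration.** The shipped presets encode the three reported
populations: n = 22/205/64; mean rates 19.47/2.10/3.32 Hz; mean burst
percentages ≈ 0/3.29/37.97 (cluster 2 zero-inflated with 81/205 bursting);
AP durations 1.54/2.79/3.00 ms; Δt₁ 0.60/1.01/1.11 ms (via ratios
0.390/0.362/0.370); notch prevalences 1/22, 102/205, 34/64; 600 s windows.
Only means and counts are published; dispersions are package choices, set
narrower than the recorded population spreads so that (a) small-n group
means are stable recovery targets (cluster-1 rate σ₁₀ = 0.10 gives a
sampled-mean SEM near 5% at n = 22), (b) the >10 Hz pre-filter is
unambiguous (rates truncated above/below 10 Hz per population), and (c) the
two putative-DA populations separate in burst activity the way the
published scatter does — bursters of the low-burst population truncated
below 13%, the high-burst population above 24.5%, on either side of the
published 17.5% boundary. Rate and burst draws are truncated log-normals
whose location is solved numerically so the *truncated* mean equals the
target, keeping recovery targets exact under truncation. The generator
emulates stationary recordings with exact rule-compliant bursts and
template waveforms; it does not emulate drift, sorting contamination,
bimodal ISI structure within bursts, or waveform variability beyond the
template family — so passing recovery tests certify the pipeline's
correctness on clean, stationary data, not robustness to recording
pathology.

## Determinism and numerics

All randomness flows through one `numpy` Generator seeded per run; repeated
runs with the same config and seed write byte-identical reports (floats are
rounded to 10 decimals in JSON; no timestamps are recorded, provenance is a
config hash + seed + version). Agglomerative clustering itself has no
randomness; index computations are seed-free. Min–max scaling maps
constant columns to 0 with a logged warning. Degenerate inputs fail fast
with the neuron id in the message: silent trains (CV undefined), < 2
spikes, windows < 60 s, flat waveforms, missing waveforms, unsorted or
duplicated timestamps.

## Problem sizes

Default test and acceptance runs use the study-sized cohorts (291 or 269
neurons, 600 s trains at 2–20 Hz, waveforms at 0.01 ms resolution), 50
replicates for clustering-recovery statistics, 10⁴ random trains for the
burst-rule oracle, and exhaustive 2×2 tables with margins ≤ 12 for the
chi-square oracle.
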