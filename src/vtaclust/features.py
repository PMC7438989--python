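"""Per-neuron electrophysiological features.

Six features characterize each neuron, following standard practice for
in vivo extracellular recordings of midbrain neurons:

1. mean firing rate (Hz),
2. coefficient of variation of the binned firing rate (regularity index),
3. percentage of spikes in bursts (%SIB) under the classical 80/160 ms
   interspike-interval rule of Grace & Bunney,
4. total AP duration (ms),
5. delta-t1 (ms): depolarization onset to end of repolarization,
6. presence of a notched AP waveform (binary).

Burst rule. A burst opens when two consecutive spikes fall within 80 ms,
extends while the next interspike interval (ISI) stays below 160 ms, and is
terminated by a silence of at least 160 ms. The terminating silence is part
of the definition: a burst still open at the end of the recording is kept
only when the observable trailing silence (window end minus last spike)
reaches 160 ms, otherwise it is discarded as unterminated. This convention
makes sustained fast regular firing (mean ISI < 80 ms, no 160 ms pauses)
correctly score ~0 %SIB rather than one recording-long "burst".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import RecordingSession, SpikeTrain, ValidationError, Waveform


class FeatureError(ValueError):
    """Feature undefined for this input."""


# ---------------------------------------------------------------------------
# firing pattern
# ---------------------------------------------------------------------------

def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count divided by window duration, in Hz."""
    if train.duration <= 0:
        raise FeatureError(f"{train.neuron_id}: zero-duration window")
    return train.n_spikes / train.duration


def firing_rate_cv(train: SpikeTrain, bin_width: float = 10.0) -> float:
    """SD/mean of firing rates in consecutive *bin_width*-second bins.

    The window is partitioned into full bins only (a trailing partial bin is
    discarded); the SD is the sample SD (n-1 denominator).
    """
    n_bins = int(train.duration // bin_width)
    if n_bins < 2:
        raise FeatureError(
            f"{train.neuron_id}: window ({train.duration:g}s) shorter than "
            f"2 bins of {bin_width:g}s"
        )
    edges = train.window_start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.timestamps, bins=edges)
    rates = counts / bin_width
    mean = rates.mean()
    if mean == 0:
        raise FeatureError(f"{train.neuron_id}: CV undefined for silent train")
    return float(rates.std(ddof=1) / mean)


@dataclass(frozen=True)
class BurstAnnotation:
    """Detected bursts as inclusive spike-index ranges, plus %SIB."""

    bursts: tuple[tuple[int, int], ...]
    n_spikes_in_bursts: int
    n_spikes_total: int

    @property
    def pct_sib(self) -> float:
        if self.n_spikes_total == 0:
            return 0.0
        return 100.0 * self.n_spikes_in_bursts / self.n_spikes_total


def detect_bursts(
    train: SpikeTrain,
    onset_max_isi: float = 80.0,
    offset_min_isi: float = 160.0,
) -> BurstAnnotation:
    """Detect bursts with the 80/160 ms ISI rule (boundaries inclusive).

    Parameters are in milliseconds. Implementation: spikes are split into
    runs separated by ISIs >= *offset_min_isi* (observed silences). Within a
    run, the burst starts at the first spike pair with ISI <= *onset_max_isi*
    and — since every later ISI in the run is < *offset_min_isi* — extends to
    the run's end. The final run only counts if the trailing window silence
    reaches *offset_min_isi* (see module docstring).
    """
    if onset_max_isi >= offset_min_isi:
        raise FeatureError(
            f"onset_max_isi ({onset_max_isi}) must be < offset_min_isi ({offset_min_isi})"
        )
    t = train.timestamps
    n = t.size
    if n < 2:
        return BurstAnnotation((), 0, n)
    # 1 ns slack so the inclusive 80/160 ms boundaries survive floating-point
    # subtraction (e.g. 0.240 - 0.080 < 0.160 in binary floats)
    eps = 1e-9
    onset_s = onset_max_isi / 1000.0 + eps
    offset_s = offset_min_isi / 1000.0 - eps
    isi = np.diff(t)
    # run boundaries: ISIs that are observed terminating silences
    breaks = np.nonzero(isi >= offset_s)[0]           # isi[i] separates i and i+1
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [n - 1]))          # inclusive
    bursts: list[tuple[int, int]] = []
    n_in = 0
    for s, e in zip(starts, ends):
        if e == n - 1 and train.window_end - t[-1] < offset_s:
            break  # unterminated final run: no observable 160 ms silence
        if e == s:
            continue
        short = np.nonzero(isi[s:e] <= onset_s)[0]
        if short.size:
            b0 = s + int(short[0])
            bursts.append((b0, int(e)))
            n_in += e - b0 + 1
    return BurstAnnotation(tuple(bursts), n_in, n)


# ---------------------------------------------------------------------------
# AP waveform morphometrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APMetrics:
    """Waveform landmarks and durations (ms); notch presence and phase."""

    ap_duration: float
    dt1: float
    notch: bool
    notch_phase: str  # "rise" | "fall" | "none"
    landmarks: dict = field(default_factory=dict)


def waveform_metrics(
    w: Waveform,
    noise_k: float = 3.0,
    notch_prominence_frac: float = 0.05,
) -> APMetrics:
    """Measure AP duration, delta-t1 and notch presence from a mean waveform.

    Baseline and noise come from the pre-trigger segment. The baseline band
    is ``noise_k`` noise SDs, floored at 1% of the peak excursion so that
    (near-)noiseless averaged traces have a finite band. Landmarks:

    * onset — last sample inside the band before the principal extremum;
    * principal peak — largest ``|v - baseline|`` extremum after the trigger;
    * trough — largest opposite-sign excursion after the peak;
    * delta-t1 — onset to first return into the band after the trough;
    * AP duration — onset to the last sample outside the band (captures the
      after-potential).

    A notch is a local-extremum pair of prominence at least
    ``notch_prominence_frac`` of the peak-to-trough amplitude, between onset
    and peak ("rise") or between peak and trough ("fall").
    """
    if w.trigger_index < 8:
        raise FeatureError(f"{w.neuron_id}: need >= 8 pre-trigger baseline samples")
    pre = w.samples[: w.trigger_index]
    baseline = pre.mean()
    noise = pre.std(ddof=1)
    v = w.samples - baseline
    amp = np.abs(v).max()
    if amp <= noise_k * noise or amp == 0:
        raise FeatureError(f"{w.neuron_id}: no AP detected above noise")
    band = max(noise_k * noise, 0.01 * amp)

    dt = w.sampling_interval
    peak = w.trigger_index + int(np.abs(v[w.trigger_index:]).argmax())
    sign = np.sign(v[peak])

    inside = np.nonzero(np.abs(v[:peak]) <= band)[0]
    if inside.size == 0:
        raise FeatureError(f"{w.neuron_id}: no baseline segment before the AP")
    onset = int(inside[-1])

    after = -sign * v[peak + 1 :]
    if after.size == 0 or after.max() <= 0:
        raise FeatureError(f"{w.neuron_id}: no repolarization trough after the peak")
    trough = peak + 1 + int(after.argmax())

    ret = np.nonzero(np.abs(v[trough:]) <= band)[0]
    if ret.size == 0:
        raise FeatureError(f"{w.neuron_id}: waveform never returns to baseline")
    ret_idx = trough + int(ret[0])
    dt1 = (ret_idx - onset) * dt

    outside = np.nonzero(np.abs(v) > band)[0]
    end_idx = int(outside[-1])
    ap_duration = max((end_idx - onset) * dt, dt1)

    p2t = abs(v[peak] - v[trough])
    thr = notch_prominence_frac * p2t

    def _has_notch(seg: np.ndarray) -> bool:
        if seg.size < 3:
            return False
        up, _ = find_peaks(seg, prominence=thr)
        dn, _ = find_peaks(-seg, prominence=thr)
        return bool(up.size or dn.size)

    notch, phase = False, "none"
    if _has_notch(v[onset : peak + 1]):
        notch, phase = True, "rise"
    elif _has_notch(v[peak : trough + 1]):
        notch, phase = True, "fall"

    landmarks = {
        "onset_ms": onset * dt,
        "peak_ms": peak * dt,
        "trough_ms": trough * dt,
        "return_ms": ret_idx * dt,
        "end_ms": end_idx * dt,
    }
    return APMetrics(float(ap_duration), float(dt1), notch, phase, landmarks)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The six features the clustering consumes, for one neuron."""

    neuron_id: str
    firing_rate: float
    cv: float
    pct_sib: float
    ap_duration: float
    dt1: float
    notch: int

    def __post_init__(self) -> None:
        vals = (self.firing_rate, self.cv, self.pct_sib, self.ap_duration, self.dt1)
        if not all(np.isfinite(vals)):
            raise ValidationError(f"{self.neuron_id}: non-finite feature")
        if self.firing_rate < 0 or self.cv < 0 or not 0 <= self.pct_sib <= 100:
            raise ValidationError(f"{self.neuron_id}: feature out of range")


#: Minimum stable epoch accepted for feature extraction, seconds.
MIN_WINDOW_S = 60.0


def extract_features(
    session: RecordingSession,
    bin_width: float = 10.0,
    onset_max_isi: float = 80.0,
    offset_min_isi: float = 160.0,
    noise_k: float = 3.0,
    notch_prominence_frac: float = 0.05,
) -> FeatureVector:
    """Assemble the six-feature vector for one recording session.

    Requires a waveform and a train of >= 2 spikes over >= 60 s (short or
    near-empty epochs do not support stable rate/CV/burst estimates).
    """
    nid = session.neuron_id
    train = session.spike_train
    if session.waveform is None:
        raise FeatureError(f"{nid}: waveform required for feature extraction")
    if train.n_spikes < 2:
        raise FeatureError(f"{nid}: need >= 2 spikes for feature extraction")
    if train.duration < MIN_WINDOW_S:
        raise FeatureError(
            f"{nid}: window {train.duration:g}s < {MIN_WINDOW_S:g}s minimum"
        )
    try:
        rate = mean_firing_rate(train)
        cv = firing_rate_cv(train, bin_width=bin_width)
        bursts = detect_bursts(train, onset_max_isi, offset_min_isi)
        ap = waveform_metrics(session.waveform, noise_k, notch_prominence_frac)
    except FeatureError:
        raise
    except Exception as exc:  # re-raise with neuron context
        raise FeatureError(f"{nid}: {exc}") from exc
    return FeatureVector(
        neuron_id=nid,
        firing_rate=rate,
        cv=cv,
        pct_sib=bursts.pct_sib,
        ap_duration=ap.ap_duration,
        dt1=ap.dt1,
        notch=int(ap.notch),
    )


def extract_feature_frame(sessions, **kwargs):
    """Six-feature DataFrame (rows = neuron ids, canonical column order)
    for a list of sessions. Keyword arguments pass to
    :func:`extract_features`."""
    import pandas as pd

    rows = [extract_features(s, **kwargs) for s in sessions]
    frame = pd.DataFrame(
        {r.neuron_id: [r.firing_rate, r.cv, r.pct_sib, r.ap_duration, r.dt1, r.notch]
         for r in rows},
        index=["firing_rate_hz", "cv", "pct_sib", "ap_dur_ms", "dt1_ms", "notch"],
    ).T.sort_index()
    frame.index.name = "neuron_id"
    return frame
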