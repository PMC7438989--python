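"""Seeded synthetic cohorts with exactly-known ground truth.

Spike trains are built from an explicit event process rather than fitted to
one: each event is either a burst (2-6 spikes, intra-burst ISIs <= 80 ms) or
a single spike, and events are separated by silences of at least 170 ms.
Because every intra-burst ISI satisfies the burst-onset bound and every
inter-event gap exceeds the 160 ms termination bound with margin, the
80/160 ms detector recovers the constructed burst labels exactly, and the
percentage of spikes in bursts is analytically controlled through the burst
probability per event.

High-firing neurons (>10 Hz) cannot be built this way — at such rates the
mean ISI is below the 170 ms floor — so they use a regular "pacemaker"
construction (gamma ISIs with high shape). Under the burst rule such trains
contain no terminated burst (there are no 160 ms silences), so their
detected burst percentage is ~0, as reported for fast-firing, putatively
GABAergic units.

AP waveforms come from a canonical biphasic template (positive lobe,
negative lobe, small after-potential bump) whose two time scales are
calibrated by fixed-point iteration against :func:`waveform_metrics` until
the measured AP duration and delta-t1 hit their targets (to within one
sampling interval, the quantization limit of the measurement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .features import BurstAnnotation, detect_bursts, waveform_metrics
from .io import RecordingSession, SpikeTrain, Waveform


class GenerationError(ValueError):
    """Requested parameters cannot be realized."""


# ---------------------------------------------------------------------------
# truncated distributions (population-level parameter draws)
# ---------------------------------------------------------------------------

def truncated_lognormal_mu(target_mean: float, sigma10: float,
                           lo: float, hi: float) -> float:
    """Location mu (log10) such that the [lo, hi]-truncated log-normal has
    the requested arithmetic mean.

    Closed form for the truncated log-normal mean, solved with Brent's
    method. Used so preset targets stay exact under truncation.
    """
    if not (lo < target_mean < hi):
        raise GenerationError(f"target mean {target_mean} outside bounds ({lo}, {hi})")
    eta = sigma10 * math.log(10)

    def trunc_mean(mu10: float) -> float:
        m = mu10 * math.log(10)
        a = (math.log(lo) - m) / eta
        b = (math.log(hi) - m) / eta
        z = norm.cdf(b) - norm.cdf(a)
        if z <= 0:
            return lo if a > 0 else hi
        return math.exp(m + eta**2 / 2) * (norm.cdf(b - eta) - norm.cdf(a - eta)) / z

    return brentq(lambda mu: trunc_mean(mu) - target_mean,
                  math.log10(lo) - 2, math.log10(hi) + 2, xtol=1e-12)


def _draw_trunc_lognormal(rng: np.random.Generator, mu10: float, sigma10: float,
                          lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        x = 10 ** rng.normal(mu10, sigma10, size=2 * (size - filled) + 8)
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, size - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


def _draw_trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                       lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        x = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, size - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def burst_probability(pct_sib: float, mean_burst_size: float) -> float:
    """Per-event burst probability realizing a target %SIB.

    Solves  pct/100 = p_b*E[k] / (p_b*E[k] + 1 - p_b)  for p_b.
    """
    s = pct_sib / 100.0
    if not 0 <= s <= 1:
        raise GenerationError(f"pct_sib {pct_sib} outside [0, 100]")
    if s == 0:
        return 0.0
    return s / (mean_burst_size * (1 - s) + s)


def generate_spike_train(
    rate_hz: float,
    pct_sib: float,
    *,
    burst_sizes: dict[int, float] | None = None,
    intra_burst_isi_ms: tuple[float, float] = (30.0, 75.0),
    min_gap_ms: float = 170.0,
    gap_shape: float = 3.0,
    duration_s: float = 600.0,
    rng: np.random.Generator | int | None = None,
    neuron_id: str = "",
) -> tuple[SpikeTrain, BurstAnnotation]:
    """Build an event-based train with an exactly-known burst annotation.

    Returns the train and its ground-truth :class:`BurstAnnotation`, which
    :func:`detect_bursts` reproduces index-for-index (construction
    guarantee: intra-burst ISIs <= 80 ms, inter-event gaps >= 170 ms).
    Inter-event gaps are min_gap + Gamma(shape, scale), with the scale set so
    the expected overall spike rate matches *rate_hz*.
    """
    rng = np.random.default_rng(rng)
    if burst_sizes is None:
        burst_sizes = {2: 0.35, 3: 0.25, 4: 0.18, 5: 0.12, 6: 0.10}
    sizes = np.array(sorted(burst_sizes))
    probs = np.array([burst_sizes[k] for k in sizes], dtype=float)
    probs /= probs.sum()
    if sizes.min() < 2:
        raise GenerationError("burst sizes must be >= 2 spikes")
    lo_isi, hi_isi = (x / 1000.0 for x in intra_burst_isi_ms)
    if not 0 < lo_isi <= hi_isi <= 0.080:
        raise GenerationError("intra-burst ISIs must lie in (0, 80] ms")
    min_gap = min_gap_ms / 1000.0
    if min_gap < 0.170:
        raise GenerationError("min_gap must be >= 170 ms to clear the 160 ms rule")

    ek = float(probs @ sizes)
    p_b = burst_probability(pct_sib, ek)
    spikes_per_event = p_b * ek + (1 - p_b)
    mean_intra = (lo_isi + hi_isi) / 2
    burst_time = p_b * (ek - 1) * mean_intra
    mean_gap = spikes_per_event / rate_hz - burst_time
    if mean_gap < min_gap - 1e-12:
        max_rate = spikes_per_event / (min_gap + burst_time)
        raise GenerationError(
            f"{neuron_id}: rate {rate_hz:g} Hz infeasible for pct_sib {pct_sib:g}% "
            f"with min_gap {min_gap_ms:g} ms (max feasible rate {max_rate:.2f} Hz)"
        )
    scale = max(mean_gap - min_gap, 0.0) / gap_shape

    times: list[float] = []
    bursts: list[tuple[int, int]] = []
    while True:
        gap = min_gap + (rng.gamma(gap_shape, scale) if scale > 0 else 0.0)
        t0 = (times[-1] if times else 0.0) + gap if times else gap
        if t0 > duration_s:
            break
        if rng.random() < p_b:
            k = int(rng.choice(sizes, p=probs))
            isis = rng.uniform(lo_isi, hi_isi, size=k - 1)
            ev = t0 + np.concatenate(([0.0], np.cumsum(isis)))
            kept = ev[ev <= duration_s]
            if kept.size == 0:
                break
            start = len(times)
            times.extend(kept.tolist())
            if kept.size >= 2:
                bursts.append((start, len(times) - 1))
            if kept.size < ev.size:
                break
        else:
            times.append(t0)

    # ground truth honors the same end-of-window rule as the detector: the
    # final burst needs an observable >= 160 ms trailing silence
    if bursts and bursts[-1][1] == len(times) - 1 and times:
        if duration_s - times[-1] < 0.160:
            bursts.pop()

    train = SpikeTrain(np.array(times), 0.0, duration_s, neuron_id)
    n_in = sum(e - s + 1 for s, e in bursts)
    truth = BurstAnnotation(tuple(bursts), n_in, len(times))
    return train, truth


def pacemaker_train(
    rate_hz: float,
    *,
    shape: float = 100.0,
    duration_s: float = 600.0,
    rng: np.random.Generator | int | None = None,
    neuron_id: str = "",
) -> SpikeTrain:
    """Regular tonic train: gamma-renewal ISIs with high shape (CV ~ 0.1).

    Emulates fast-firing, putatively GABAergic units. At >10 Hz the ISI
    distribution contains neither 160 ms silences nor (for rates near the
    boundary) reliably sub-80 ms pairs ending in silences, so the 80/160 ms
    detector reports ~0% spikes in bursts.
    """
    rng = np.random.default_rng(rng)
    n_guess = int(rate_hz * duration_s * 1.3) + 100
    t = np.cumsum(rng.gamma(shape, 1.0 / (rate_hz * shape), size=n_guess))
    while t.size and t[-1] < duration_s:
        t = np.concatenate([t, t[-1] + np.cumsum(
            rng.gamma(shape, 1.0 / (rate_hz * shape), size=n_guess))])
    return SpikeTrain(t[t <= duration_s], 0.0, duration_s, neuron_id)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

_TROUGH_AMP = 0.6     # negative lobe amplitude relative to the peak
_AFTER_AMP = 0.12     # after-potential bump amplitude
_RISE_FRAC = 0.5      # fraction of delta-t1 taken by the positive lobe


def _render_template(b_ms: float, w_ms: float, sampling_interval_ms: float,
                     n_pre: int, notch_phase: str = "none",
                     notch_depth: float = 0.0) -> np.ndarray:
    """Sample the canonical biphasic template (baseline-padded, noiseless).

    *notch_depth* is the amplitude of a Gaussian dip subtracted mid-way
    through the rising (onset-to-peak) or falling (peak-to-trough) limb.
    """
    dt = sampling_interval_ms
    r = _RISE_FRAC * b_ms            # positive lobe length
    f = b_ms - r                     # negative lobe length
    n_post = int(np.ceil((b_ms + w_ms) / dt)) + 24
    t = np.arange(n_post) * dt
    v = np.zeros(n_post)
    m = t < r
    v[m] = np.sin(np.pi * t[m] / r)
    m = (t >= r) & (t < b_ms)
    v[m] = -_TROUGH_AMP * np.sin(np.pi * (t[m] - r) / f)
    m = (t >= b_ms) & (t < b_ms + w_ms)
    v[m] = _AFTER_AMP * np.sin(np.pi * (t[m] - b_ms) / w_ms)
    if notch_depth > 0:
        peak_t = r / 2                         # apex of the positive lobe
        trough_t = r + f / 2
        if notch_phase == "rise":
            # dip just below the apex, where the limb is shallow: a modest
            # depth yields a clean local-extremum pair without touching the
            # baseline band
            center = 0.45 * r
            width = max(r / 8, 2.0 * dt)
            v -= notch_depth * np.exp(-0.5 * ((t - center) / width) ** 2)
        else:
            # brief re-rise shortly before the trough, where the limb
            # flattens (an added bump keeps the true trough as the deepest
            # point and leaves the baseline-return landmark untouched)
            span = trough_t - peak_t
            center = peak_t + 0.85 * span
            width = max(0.08 * span, 2.0 * dt)
            v += notch_depth * np.exp(-0.5 * ((t - center) / width) ** 2)
    return np.concatenate([np.zeros(n_pre), v])


def _notch_prominence(samples: np.ndarray, dt: float, n_pre: int) -> float:
    """Largest interior local-extremum prominence on the rise or fall limb,
    segmented exactly the way the feature extractor segments the waveform."""
    from scipy.signal import find_peaks

    m = waveform_metrics(Waveform(samples, dt, n_pre))
    onset = round(m.landmarks["onset_ms"] / dt)
    peak = round(m.landmarks["peak_ms"] / dt)
    trough = round(m.landmarks["trough_ms"] / dt)
    best = 0.0
    for seg in (samples[onset : peak + 1], samples[peak : trough + 1]):
        for sgn in (seg, -seg):
            _, props = find_peaks(sgn, prominence=0.0)
            if props["prominences"].size:
                best = max(best, float(props["prominences"].max()))
    return best


def generate_waveform(
    ap_duration_ms: float,
    dt1_ms: float,
    notch: bool = False,
    notch_phase: str = "rise",
    *,
    sampling_interval_ms: float = 0.01,
    noise_sd: float = 0.0,
    notch_frac: float = 0.10,
    n_pre: int = 64,
    rng: np.random.Generator | int | None = None,
    neuron_id: str = "",
) -> Waveform:
    """Waveform whose measured AP duration and delta-t1 match the targets.

    The template's two time scales (end of repolarization, after-potential
    length) are corrected iteratively against :func:`waveform_metrics` on the
    noiseless trace until both durations land within one sampling interval
    (or 0.5%, whichever is larger) of target; Gaussian noise (SD in units of
    the unit peak) is added last.
    """
    if not 0 < dt1_ms < ap_duration_ms:
        raise GenerationError(f"{neuron_id}: need 0 < dt1 < ap_duration")
    ratio = dt1_ms / ap_duration_ms
    if not 0.10 <= ratio <= 0.90:
        raise GenerationError(
            f"{neuron_id}: dt1/ap ratio {ratio:.2f} outside the template's range"
        )
    if sampling_interval_ms > dt1_ms / 10:
        raise GenerationError(f"{neuron_id}: sampling_interval > dt1/10")

    dt = sampling_interval_ms
    # measured durations are quantized to the sampling grid, and the two
    # time scales are coupled through it, so each duration is matched to
    # within one sampling interval (or 0.5%, whichever is larger)
    tol_d = max(0.005, 1.05 * dt / dt1_ms)
    tol_w = max(0.005, 1.05 * dt / (ap_duration_ms - dt1_ms))
    b, w = dt1_ms, ap_duration_ms - dt1_ms
    best: tuple[float, float, float] | None = None
    for _ in range(40):
        samples = _render_template(b, w, dt, n_pre)
        m = waveform_metrics(Waveform(samples, dt, n_pre, neuron_id))
        err_d = m.dt1 / dt1_ms
        err_w = (m.ap_duration - m.dt1) / (ap_duration_ms - dt1_ms)
        score = max(abs(err_d - 1) / tol_d, abs(err_w - 1) / tol_w)
        if best is None or score < best[0]:
            best = (score, b, w)
        if score < 1.0:
            break
        b /= err_d ** 0.7            # damped multiplicative correction
        w /= max(err_w, 1e-6) ** 0.7
    if best is None or best[0] >= 1.0:
        raise GenerationError(
            f"{neuron_id}: template calibration failed for "
            f"ap={ap_duration_ms:g} dt1={dt1_ms:g}"
        )
    _, b, w = best

    depth = 0.0
    if notch:
        # bisect the dip depth until the realized local-extremum prominence
        # matches the requested fraction of the peak-to-trough amplitude
        base = _render_template(b, w, dt, n_pre)
        mm = waveform_metrics(Waveform(base, dt, n_pre, neuron_id))
        peak_i = round(mm.landmarks["peak_ms"] / dt)
        trough_i = round(mm.landmarks["trough_ms"] / dt)
        p2t = float(base[peak_i] - base[trough_i])
        target = notch_frac * p2t
        lo_d, hi_d = 0.0, 0.45 * p2t   # cap keeps landmarks intact
        for _ in range(50):
            depth = (lo_d + hi_d) / 2
            prom = _notch_prominence(
                _render_template(b, w, dt, n_pre, notch_phase, depth), dt, n_pre)
            if abs(prom - target) < 0.03 * target:
                break
            if prom < target:
                lo_d = depth
            else:
                hi_d = depth
        else:
            raise GenerationError(
                f"{neuron_id}: cannot realize a {notch_frac:.0%}-prominence notch"
            )

    samples = _render_template(b, w, dt, n_pre, notch_phase, depth)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
    return Waveform(samples, dt, n_pre, neuron_id)


# ---------------------------------------------------------------------------
# population presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationPreset:
    """Generative parameters of one neuron class.

    ``construction`` is "events" (burst-controlled, rates < ~5.9 Hz) or
    "pacemaker" (regular tonic, high rates). ``pct_sib`` holds the
    zero-inflated mixture for events presets: a fraction of bursting neurons
    and a truncated log-normal for the bursters' %SIB.
    """

    name: str
    n_neurons: int
    construction: str
    rate: dict
    ap_duration: dict
    dt1_ratio: dict
    notch_probability: float
    pct_sib: dict | None = None
    burst_sizes: dict[int, float] = field(
        default_factory=lambda: {2: 0.35, 3: 0.25, 4: 0.18, 5: 0.12, 6: 0.10})
    intra_burst_isi_ms: tuple[float, float] = (30.0, 75.0)
    min_gap_ms: float = 170.0
    gap_shape: float = 3.0
    pacemaker_shape: float = 100.0
    duration_s: float = 600.0
    sampling_interval_ms: float = 0.01
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.construction not in ("events", "pacemaker"):
            raise GenerationError(f"unknown construction {self.construction!r}")
        if self.construction == "events" and self.pct_sib is None:
            raise GenerationError(f"{self.name}: events preset needs pct_sib")
        if not 0 <= self.notch_probability <= 1:
            raise GenerationError(f"{self.name}: notch_probability outside [0, 1]")
        lo, hi = self.intra_burst_isi_ms
        if not 0 < lo <= hi <= 80:
            raise GenerationError(f"{self.name}: intra-burst ISIs must lie in (0, 80] ms")
        if self.min_gap_ms < 170:
            raise GenerationError(f"{self.name}: min_gap must be >= 170 ms")


@dataclass
class SyntheticNeuron:
    """A generated recording plus its ground truth."""

    session: RecordingSession
    true_label: str
    true_bursts: BurstAnnotation
    true_rate_hz: float
    true_ap_ms: float
    true_dt1_ms: float
    true_notch: bool

    @property
    def true_pct_sib(self) -> float:
        return self.true_bursts.pct_sib

    @property
    def neuron_id(self) -> str:
        return self.session.neuron_id


def load_presets(path: str | Path) -> list[PopulationPreset]:
    """Load presets from a YAML file (list of preset mappings)."""
    raw = yaml.safe_load(Path(path).read_text())
    out = []
    for item in raw:
        if "burst_sizes" in item:
            item["burst_sizes"] = {int(k): float(v) for k, v in item["burst_sizes"].items()}
        if "intra_burst_isi_ms" in item:
            item["intra_burst_isi_ms"] = tuple(item["intra_burst_isi_ms"])
        out.append(PopulationPreset(**item))
    return out


def paper_presets() -> list[PopulationPreset]:
    """The three shipped population presets (high-firing; low-firing
    low-burst; low-firing high-burst), calibrated to the published cohort."""
    with resources.as_file(resources.files("vtaclust") / "presets" / "paper.yaml") as p:
        return load_presets(p)


def generate_population(
    presets: list[PopulationPreset],
    seed: int | np.random.Generator | None = None,
) -> list[SyntheticNeuron]:
    """Draw a full cohort: per-neuron parameters from each preset, then
    trains and waveforms. Fully reproducible under *seed*.

    Rates and bursters' %SIB are truncated log-normal with the location
    calibrated so the truncated mean equals the preset target; delta-t1 is
    drawn as a ratio of the AP duration, which produces the linear AP-dt1
    relationship seen across real cohorts.
    """
    rng = np.random.default_rng(seed)
    cohort: list[SyntheticNeuron] = []
    for preset in presets:
        n = preset.n_neurons
        r = preset.rate
        mu = truncated_lognormal_mu(r["mean"], r["sigma10"], r["lo"], r["hi"])
        rates = _draw_trunc_lognormal(rng, mu, r["sigma10"], r["lo"], r["hi"], n)

        if preset.construction == "events":
            p = preset.pct_sib
            is_burster = rng.random(n) < p["burst_fraction"]
            mu_b = truncated_lognormal_mu(p["mean"], p["sigma10"], p["lo"], p["hi"])
            pct = np.where(
                is_burster,
                _draw_trunc_lognormal(rng, mu_b, p["sigma10"], p["lo"], p["hi"], n),
                0.0,
            )
        else:
            pct = np.zeros(n)

        a = preset.ap_duration
        aps = _draw_trunc_normal(rng, a["mean"], a["sd"], a["lo"], a["hi"], n)
        rt = preset.dt1_ratio
        ratios = _draw_trunc_normal(rng, rt["mean"], rt["sd"], rt["lo"], rt["hi"], n)
        dt1s = aps * ratios
        notches = rng.random(n) < preset.notch_probability
        phases = np.where(rng.random(n) < 0.5, "rise", "fall")

        for i in range(n):
            nid = f"{preset.name}-{i:03d}"
            if preset.construction == "events":
                train, truth = generate_spike_train(
                    float(rates[i]), float(pct[i]),
                    burst_sizes=preset.burst_sizes,
                    intra_burst_isi_ms=preset.intra_burst_isi_ms,
                    min_gap_ms=preset.min_gap_ms,
                    gap_shape=preset.gap_shape,
                    duration_s=preset.duration_s,
                    rng=rng, neuron_id=nid,
                )
            else:
                train = pacemaker_train(
                    float(rates[i]), shape=preset.pacemaker_shape,
                    duration_s=preset.duration_s, rng=rng, neuron_id=nid,
                )
                # regular tonic trains carry no constructed bursts; the
                # annotation is measured, and is ~empty by construction
                truth = detect_bursts(train)
            wf = generate_waveform(
                float(aps[i]), float(dt1s[i]),
                notch=bool(notches[i]), notch_phase=str(phases[i]),
                sampling_interval_ms=preset.sampling_interval_ms,
                noise_sd=preset.noise_sd, rng=rng, neuron_id=nid,
            )
            session = RecordingSession(train, wf, {"preset": preset.name})
            cohort.append(SyntheticNeuron(
                session, preset.name, truth,
                float(rates[i]), float(aps[i]), float(dt1s[i]), bool(notches[i]),
            ))
    return cohort


def ground_truth_frame(cohort: list[SyntheticNeuron]) -> pd.DataFrame:
    """Ground-truth table (indexed by neuron_id) for a generated cohort."""
    rows = {
        s.neuron_id: {
            "true_label": s.true_label,
            "true_rate_hz": s.true_rate_hz,
            "true_pct_sib": s.true_pct_sib,
            "true_ap_ms": s.true_ap_ms,
            "true_dt1_ms": s.true_dt1_ms,
            "true_notch": int(s.true_notch),
        }
        for s in cohort
    }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "neuron_id"
    return df
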