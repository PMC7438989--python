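"""Plain-text input/output for single-unit recordings and feature tables.

A recording is stored as a small bundle of diffable text files sharing one
basename (the neuron id)::

    <id>.spikes.txt     one spike timestamp (seconds) per line,
                        or a CSV with a column named "t_s"
    <id>.waveform.csv   mean AP waveform, columns "t_ms,v"   (optional)
    <id>.meta.json      window, trigger index, free metadata (optional)

A cohort is a directory of such bundles plus an ``index.csv`` listing the
neuron ids (and, for synthetic cohorts, ground-truth columns).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the per-neuron feature table consumed by the clustering.
FEATURE_COLUMNS = ("firing_rate_hz", "cv", "pct_sib", "ap_dur_ms", "dt1_ms", "notch")


class ValidationError(ValueError):
    """A file or object violates a documented invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered single-unit spike timestamps within a recording window.

    Timestamps are in seconds, strictly increasing, and contained in
    ``[window_start, window_end]``.
    """

    timestamps: np.ndarray
    window_start: float
    window_end: float
    neuron_id: str = ""

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise ValidationError(f"{self.neuron_id}: timestamps must be 1-D")
        if not np.isfinite(ts).all():
            raise ValidationError(f"{self.neuron_id}: non-finite timestamp")
        if self.window_end - self.window_start <= 0:
            raise ValidationError(
                f"{self.neuron_id}: window duration must be positive "
                f"({self.window_start}..{self.window_end})"
            )
        if ts.size:
            bad = np.nonzero(np.diff(ts) <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"{self.neuron_id}: timestamps not strictly increasing "
                    f"at line {bad[0] + 2} (t={ts[bad[0] + 1]:g} after t={ts[bad[0]]:g})"
                )
            if ts[0] < self.window_start or ts[-1] > self.window_end:
                raise ValidationError(
                    f"{self.neuron_id}: timestamps outside window "
                    f"[{self.window_start}, {self.window_end}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        """Window duration in seconds."""
        return self.window_end - self.window_start


@dataclass(frozen=True)
class Waveform:
    """Averaged extracellular AP voltage trace, uniformly sampled.

    ``samples`` are in microvolts or any consistent relative unit;
    ``sampling_interval`` is in ms per sample. ``trigger_index`` marks the
    detection-threshold crossing; samples before it are pre-trigger baseline.
    """

    samples: np.ndarray
    sampling_interval: float
    trigger_index: int
    neuron_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", v)
        if v.ndim != 1 or v.size < 32:
            raise ValidationError(f"{self.neuron_id}: waveform needs >= 32 samples")
        if not np.isfinite(v).all():
            raise ValidationError(f"{self.neuron_id}: non-finite waveform sample")
        if self.sampling_interval <= 0:
            raise ValidationError(f"{self.neuron_id}: sampling_interval must be > 0")
        if not (0 <= self.trigger_index < v.size):
            raise ValidationError(f"{self.neuron_id}: trigger_index out of bounds")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_interval


@dataclass
class RecordingSession:
    """One neuron's spike train plus (optionally) its mean AP waveform."""

    spike_train: SpikeTrain
    waveform: Waveform | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.waveform is not None
            and self.waveform.neuron_id
            and self.spike_train.neuron_id
            and self.waveform.neuron_id != self.spike_train.neuron_id
        ):
            raise ValidationError(
                f"neuron_id mismatch: train={self.spike_train.neuron_id!r} "
                f"waveform={self.waveform.neuron_id!r}"
            )

    @property
    def neuron_id(self) -> str:
        return self.spike_train.neuron_id


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_timestamps(path: Path) -> np.ndarray:
    text = path.read_text().strip()
    if not text:
        return np.empty(0)
    first = text.splitlines()[0]
    if "t_s" in first:
        return pd.read_csv(path, float_precision="round_trip")["t_s"].to_numpy(dtype=float)
    try:
        return np.array([float(line) for line in text.splitlines() if line.strip()])
    except ValueError as exc:
        raise ValidationError(f"{path}: cannot parse timestamps ({exc})") from exc


def _read_waveform(path: Path, neuron_id: str, trigger_index: int | None) -> Waveform:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t_ms", "v"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: waveform CSV lacks columns {sorted(missing)}")
    t = df["t_ms"].to_numpy(dtype=float)
    v = df["v"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError(f"{path}: waveform time axis not uniformly sampled")
    if trigger_index is None:
        # infer the threshold crossing: first sample departing from the
        # leading-edge baseline by >10% of the full excursion
        base = v[:8].mean()
        dev = np.abs(v - base)
        crossing = np.nonzero(dev > 0.10 * dev.max())[0]
        trigger_index = int(crossing[0]) if crossing.size else 0
        logger.warning("%s: trigger_index missing, inferred %d", neuron_id, trigger_index)
    return Waveform(v, float(dt[0]), int(trigger_index), neuron_id)


def read_recording(path: str | Path) -> RecordingSession:
    """Read one neuron's bundle.

    ``path`` may be the ``*.spikes.txt`` file or a directory holding exactly
    one such file. If no sidecar metadata declares the recording window, the
    window defaults to [first spike, last spike] with a logged warning.
    """
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.glob("*.spikes.txt"))
        if len(candidates) != 1:
            raise ValidationError(
                f"{path}: expected exactly one *.spikes.txt, found {len(candidates)}"
            )
        path = candidates[0]
    if not path.exists():
        raise FileNotFoundError(path)

    base = path.name[: -len(".spikes.txt")] if path.name.endswith(".spikes.txt") else path.stem
    neuron_id = base
    meta_path = path.with_name(base + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    neuron_id = meta.get("neuron_id", neuron_id)

    ts = _read_timestamps(path)
    if ts.size >= 2:
        bad = np.nonzero(np.diff(ts) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"{neuron_id}: timestamps not strictly increasing at line "
                f"{bad[0] + 2} (t={ts[bad[0] + 1]:g} after t={ts[bad[0]]:g})"
            )
    if "window_start" in meta and "window_end" in meta:
        w0, w1 = float(meta["window_start"]), float(meta["window_end"])
    else:
        if ts.size < 2:
            raise ValidationError(f"{neuron_id}: no window metadata and < 2 spikes")
        w0, w1 = float(ts[0]), float(ts[-1])
        logger.warning(
            "%s: no recording window in metadata, defaulting to [first, last] spike",
            neuron_id,
        )
    train = SpikeTrain(ts, w0, w1, neuron_id)

    wf_path = path.with_name(base + ".waveform.csv")
    waveform = None
    if wf_path.exists():
        waveform = _read_waveform(wf_path, neuron_id, meta.get("trigger_index"))

    extra = {k: v for k, v in meta.items()
             if k not in {"neuron_id", "window_start", "window_end", "trigger_index"}}
    return RecordingSession(train, waveform, extra)


def write_recording(session: RecordingSession, directory: str | Path) -> Path:
    """Write one neuron's bundle into *directory*; returns the spikes path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nid = session.neuron_id or "neuron"
    spikes = directory / f"{nid}.spikes.txt"
    spikes.write_text(
        "".join(f"{float(t)!r}\n" for t in session.spike_train.timestamps))
    meta = {
        "neuron_id": nid,
        "window_start": session.spike_train.window_start,
        "window_end": session.spike_train.window_end,
        **session.metadata,
    }
    if session.waveform is not None:
        w = session.waveform
        meta["trigger_index"] = int(w.trigger_index)
        lines = ["t_ms,v"] + [
            f"{float(t)!r},{float(v)!r}" for t, v in zip(w.times_ms, w.samples)]
        (directory / f"{nid}.waveform.csv").write_text("\n".join(lines) + "\n")
    (directory / f"{nid}.meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return spikes


def read_cohort(directory: str | Path) -> list[RecordingSession]:
    """Read every bundle listed in ``index.csv`` (or all bundles if absent)."""
    directory = Path(directory)
    index = directory / "index.csv"
    if index.exists():
        ids = pd.read_csv(index)["neuron_id"].astype(str).tolist()
        paths = [directory / f"{nid}.spikes.txt" for nid in ids]
    else:
        paths = sorted(directory.glob("*.spikes.txt"))
    return [read_recording(p) for p in paths]


def write_cohort(
    sessions: list[RecordingSession],
    directory: str | Path,
    extra_columns: pd.DataFrame | None = None,
) -> Path:
    """Write bundles plus an ``index.csv``.

    *extra_columns* (indexed by neuron_id) lets synthetic cohorts ship their
    ground truth next to the data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = []
    for s in sessions:
        write_recording(s, directory)
        ids.append(s.neuron_id)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate neuron_id in cohort")
    index = pd.DataFrame({"neuron_id": sorted(ids)}).set_index("neuron_id")
    if extra_columns is not None:
        index = index.join(extra_columns)
    path = directory / "index.csv"
    index.reset_index().to_csv(path, index=False)
    return path


def write_feature_table(rows: list, path: str | Path) -> Path:
    """Write FeatureVectors as the canonical six-feature CSV.

    Rows are ordered by neuron_id so output bytes do not depend on input
    order. Duplicate ids and empty input are errors.
    """
    if not rows:
        raise ValidationError("no features to write")
    ids = [r.neuron_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate neuron_id: {dupes}")
    path = Path(path)
    header = "neuron_id," + ",".join(FEATURE_COLUMNS)
    lines = [header]
    for r in sorted(rows, key=lambda r: r.neuron_id):
        lines.append(
            f"{r.neuron_id},{r.firing_rate!r},{r.cv!r},{r.pct_sib!r},"
            f"{r.ap_duration!r},{r.dt1!r},{int(r.notch)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame indexed by neuron_id."""
    df = pd.read_csv(path, index_col="neuron_id")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: feature table lacks columns {sorted(missing)}")
    return df[list(FEATURE_COLUMNS)]
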