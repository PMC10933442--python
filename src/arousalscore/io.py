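"""Readers and writers for the formats the pipeline touches.

Signals travel as EDF (standard 16-bit, 1-second data records); annotations as
plain CSV (hypnogram: ``epoch_index,stage``; events: ``onset_s,duration_s,type``);
feature tables as CSV with a fixed, documented column order; reports as JSON.

Conventions: time is seconds from recording start (0-based); event windows are
half-open ``[onset, onset + duration)``; sample values are volts in memory.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("W", "N1", "N2", "N3", "REM")
#: Channels the pipeline consumes (six EEG derivations plus chin EMG).
CHANNELS = ("C3", "C4", "O1", "O2", "F3", "F4", "chin")

HYPNOGRAM_COLUMNS = ["epoch_index", "stage"]
EVENT_COLUMNS = ["onset_s", "duration_s", "type"]
#: Metadata columns preceding the 136 feature columns in a feature table.
METADATA_COLUMNS = ["event_id", "recording", "stage", "level", "onset_s", "duration_s"]


class FormatError(ValueError):
    """An input file does not match the documented format."""


@dataclass
class Recording:
    """Multichannel time series at a single sampling rate.

    Parameters
    ----------
    channels
        Mapping from channel label to a 1-D sample array in volts. All
        channels must have the same length; insertion order is preserved.
    fs
        Sampling frequency in Hz.
    start_time
        Origin of the time axis in seconds (0 by convention).
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("a recording needs at least one channel")
        lengths = {lab: len(x) for lab, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {lab: np.asarray(x, dtype=float) for lab, x in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return list(self.channels)

    def subset(self, wanted: list[str]) -> "Recording":
        missing = [w for w in wanted if w not in self.channels]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not present; available: {self.labels}"
            )
        return Recording({w: self.channels[w] for w in wanted}, self.fs, self.start_time)


@dataclass
class Hypnogram:
    """Sleep-stage labels in fixed-length epochs over {W, N1, N2, N3, REM}."""

    labels: list[str]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        bad = sorted(set(self.labels) - set(STAGES))
        if bad:
            raise FormatError(f"unknown stage symbol(s) {bad}; expected one of {STAGES}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_length

    def stage_at(self, t: float) -> str:
        """Stage of the epoch containing time ``t`` (epoch = floor(t / 30))."""
        if t < 0 or t >= self.duration:
            raise IndexError(f"time {t} s outside hypnogram of {self.duration} s")
        return self.labels[int(t // self.epoch_length)]

    def is_sleep_range(self, t0: float, t1: float) -> bool:
        """True when every epoch overlapping ``[t0, t1)`` is a non-wake stage."""
        if t0 < 0 or t1 > self.duration or t1 <= t0:
            return False
        e0 = int(t0 // self.epoch_length)
        e1 = int(np.ceil(t1 / self.epoch_length))
        return all(lab != "W" for lab in self.labels[e0:e1])


@dataclass(frozen=True)
class ArousalEvent:
    """A scorer-annotated arousal (or a sham-arousal control window).

    Real arousals must last at least 3 s (the defining criterion for an
    arousal); sham windows are stable-sleep controls and carry ``is_sham``.
    """

    onset: float
    duration: float
    stage_at_onset: str | None = None
    is_sham: bool = False

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not self.is_sham and self.duration < 3.0:
            raise ValueError(
                f"arousal duration must be >= 3 s, got {self.duration}"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_number(v: float, width: int = 8) -> bytes:
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s.encode().ljust(width)
    raise ValueError(f"cannot format {v} in {width} EDF header bytes")


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as a standard 16-bit EDF file.

    Uses 1-second data records, so the recording length must be a whole
    number of seconds and the sampling rate an integer. Samples are stored
    in microvolts with a per-channel symmetric physical range, which bounds
    the quantization error at ``phys_max / 32767`` per channel.
    """
    fs = int(round(recording.fs))
    if abs(fs - recording.fs) > 1e-9:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {recording.fs}")
    n = recording.n_samples
    if n % fs != 0:
        raise ValueError(
            f"recording length {n} is not a whole number of 1-s records at {fs} Hz"
        )
    n_records = n // fs
    labels = recording.labels
    n_sig = len(labels)

    header = b"0".ljust(8)
    header += b"X X X X".ljust(80)                      # patient id (anonymous)
    header += b"Startdate 01-JAN-2000 X X X".ljust(80)  # recording id
    header += b"01.01.00" + b"00.00.00"
    header += str(256 * (1 + n_sig)).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_records).encode().ljust(8)
    header += b"1".ljust(8)                             # record duration (s)
    header += str(n_sig).encode().ljust(4)

    phys_max: list[float] = []
    digital: list[np.ndarray] = []
    for lab in labels:
        x_uv = recording.channels[lab] * 1e6
        a = float(max(np.max(np.abs(x_uv)), 1e-3))
        phys_max.append(a)
        d = np.clip(np.round(x_uv / a * 32767.0), -32767, 32767).astype("<i2")
        digital.append(d)

    def sig_field(values, width):
        return b"".join(
            (v if isinstance(v, bytes) else str(v).encode())[:width].ljust(width)
            for v in values
        )

    header += sig_field(labels, 16)
    header += sig_field([""] * n_sig, 80)               # transducer
    header += sig_field(["uV"] * n_sig, 8)
    header += b"".join(_edf_number(-a) for a in phys_max)
    header += b"".join(_edf_number(a) for a in phys_max)
    header += sig_field([-32767] * n_sig, 8)   # symmetric digital range: the
    header += sig_field([32767] * n_sig, 8)    # phys<->dig affine has no offset
    header += sig_field([""] * n_sig, 80)               # prefiltering
    header += sig_field([fs] * n_sig, 8)
    header += sig_field([""] * n_sig, 32)

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            for d in digital:
                f.write(d[r * fs:(r + 1) * fs].tobytes())


def read_recording(path: str | Path, wanted_channels: list[str] | None = None) -> Recording:
    """Read an EDF file, returning exactly ``wanted_channels`` in volts.

    Raises
    ------
    KeyError
        If a wanted channel is absent (the message lists available labels).
    FormatError
        If the file cannot be parsed as EDF.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error paths
        raise FormatError(f"cannot read {path} as EDF: {exc}") from exc
    available = list(raw.ch_names)
    wanted = list(wanted_channels) if wanted_channels is not None else available
    missing = [w for w in wanted if w not in available]
    if missing:
        raise KeyError(f"channel(s) {missing} not in {path.name}; available: {available}")
    data = raw.get_data(picks=wanted)
    return Recording({lab: data[i] for i, lab in enumerate(wanted)}, fs=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# CSV annotations
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": range(len(hypnogram.labels)), "stage": hypnogram.labels}
    ).to_csv(path, index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    if list(df.columns) != HYPNOGRAM_COLUMNS:
        raise FormatError(
            f"hypnogram CSV must have columns {HYPNOGRAM_COLUMNS}, got {list(df.columns)}"
        )
    return Hypnogram(labels=[str(s) for s in df["stage"]])


def write_events(events: list[ArousalEvent], path: str | Path) -> None:
    rows = [
        {"onset_s": e.onset, "duration_s": e.duration, "type": "sham" if e.is_sham else "arousal"}
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list[ArousalEvent]:
    df = pd.read_csv(path)
    if list(df.columns) != EVENT_COLUMNS:
        raise FormatError(
            f"events CSV must have columns {EVENT_COLUMNS}, got {list(df.columns)}"
        )
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.onset_s < 0 or row.duration_s <= 0:
            raise FormatError(
                f"row {i}: onset must be >= 0 and duration > 0 "
                f"(got onset {row.onset_s}, duration {row.duration_s})"
            )
        if row.type not in ("arousal", "sham"):
            raise FormatError(f"row {i}: unknown event type {row.type!r}")
        events.append(
            ArousalEvent(
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                is_sham=(row.type == "sham"),
            )
        )
    return events


def read_annotations(
    hypnogram_path: str | Path, events_path: str | Path
) -> tuple[Hypnogram, list[ArousalEvent]]:
    """Load the hypnogram and the event list for one recording.

    Events come back sorted by onset with ``stage_at_onset`` filled by epoch
    lookup (epoch index = floor(onset / 30)).
    """
    hyp = read_hypnogram(hypnogram_path)
    events = read_events(events_path)
    out = []
    for e in sorted(events, key=lambda e: e.onset):
        out.append(dataclasses.replace(e, stage_at_onset=hyp.stage_at(e.onset)))
    return hyp, out


# ---------------------------------------------------------------------------
# Feature tables and reports
# ---------------------------------------------------------------------------

def feature_table_columns() -> list[str]:
    """The fixed column order of a feature CSV: metadata, then 136 features."""
    from .features import FEATURE_NAMES

    return METADATA_COLUMNS + list(FEATURE_NAMES)


def write_feature_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix with the documented, stable column order."""
    cols = feature_table_columns()
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s): {missing[:5]} ...")
    matrix[cols].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = feature_table_columns()
    if list(df.columns) != cols:
        raise FormatError("feature CSV columns do not match the documented order")
    return df


def write_report(report, path: str | Path) -> None:
    """Serialize a stage report (or any to_dict-able object) as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, sort_keys=True)
        f.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as f:
        return json.load(f)
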