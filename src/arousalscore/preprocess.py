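"""Signal conditioning: high-pass filtering, resampling, segment extraction.

The processing order is high-pass at the native rate, then resampling, then
segmentation. Filtering is zero-phase (forward-backward Butterworth), so event
morphology — which the amplitude score depends on — is preserved.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import ArousalEvent, Recording

logger = logging.getLogger(__name__)

DEFAULT_HIGHPASS_HZ = 0.3
DEFAULT_TARGET_FS = 128.0

#: Composite signals used downstream: paired EEG derivations are averaged
#: sample-wise ("C3/4" convention); chin EMG passes through.
DEFAULT_COMPOSITE_MAP: dict[str, tuple[str, ...]] = {
    "C34": ("C3", "C4"),
    "O12": ("O1", "O2"),
    "F34": ("F3", "F4"),
    "chin": ("chin",),
}


class SegmentOutOfBounds(ValueError):
    """The event (or its pre-event window) falls outside the recording."""


@dataclass
class SegmentPair:
    """An arousal window and the equal-length window immediately before it.

    Both windows are half-open: arousal ``[onset, onset + duration)``, pre
    ``[onset - duration, onset)``; per signal both have ``round(duration*fs)``
    samples.
    """

    arousal: dict[str, np.ndarray]
    pre: dict[str, np.ndarray]
    fs: float
    event: ArousalEvent

    def __post_init__(self) -> None:
        for lab in self.arousal:
            if len(self.arousal[lab]) != len(self.pre[lab]):
                raise ValueError(f"segment lengths differ for signal {lab}")


def highpass(recording: Recording, cutoff: float = DEFAULT_HIGHPASS_HZ) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass; removes DC and drift."""
    nyq = recording.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = sps.butter(4, cutoff, btype="highpass", fs=recording.fs, output="sos")
    # pad several cutoff periods: the 0.3 Hz impulse response is seconds long
    padlen = min(recording.n_samples - 1, int(3 * recording.fs / cutoff))
    out = {
        lab: sps.sosfiltfilt(sos, x, padlen=padlen)
        for lab, x in recording.channels.items()
    }
    return Recording(out, recording.fs, recording.start_time)


def resample(recording: Recording, target_fs: float = DEFAULT_TARGET_FS) -> Recording:
    """Polyphase rational resampling (anti-aliased, deterministic).

    200 -> 128 Hz reduces to the rational factor 16/25. When ``target_fs``
    equals the current rate the samples are returned unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if abs(target_fs - recording.fs) < 1e-12:
        return Recording(
            {lab: x.copy() for lab, x in recording.channels.items()},
            recording.fs,
            recording.start_time,
        )
    frac = Fraction(int(round(target_fs * 1000)), int(round(recording.fs * 1000)))
    up, down = frac.numerator, frac.denominator
    out = {lab: sps.resample_poly(x, up, down) for lab, x in recording.channels.items()}
    return Recording(out, target_fs, recording.start_time)


def make_composites(
    recording: Recording, composite_map: dict[str, tuple[str, ...]] | None = None
) -> Recording:
    """Form composite signals (e.g. C34 = mean of C3 and C4) from raw channels."""
    cmap = composite_map or DEFAULT_COMPOSITE_MAP
    out = {}
    for name, members in cmap.items():
        missing = [m for m in members if m not in recording.channels]
        if missing:
            raise KeyError(
                f"composite {name} needs channel(s) {missing}; available: {recording.labels}"
            )
        out[name] = np.mean([recording.channels[m] for m in members], axis=0)
    return Recording(out, recording.fs, recording.start_time)


def extract_segment_pair(
    recording: Recording,
    event: ArousalEvent,
    signals: list[str] | None = None,
) -> SegmentPair:
    """Cut the arousal window and the same-length pre-arousal window.

    Raises :class:`SegmentOutOfBounds` (callers skip and log the event) when
    the pre-window would start before the recording or the arousal window
    would run past its end.
    """
    labs = signals if signals is not None else recording.labels
    fs = recording.fs
    i0 = int(round(event.onset * fs))
    n = int(round(event.duration * fs))
    if n < 1:
        raise SegmentOutOfBounds(f"event at {event.onset} s has zero-length window")
    if i0 - n < 0:
        raise SegmentOutOfBounds(
            f"pre-window of event at {event.onset} s starts before the recording"
        )
    if i0 + n > recording.n_samples:
        raise SegmentOutOfBounds(
            f"event at {event.onset} s (+{event.duration} s) runs past the recording end"
        )
    arousal = {lab: recording.channels[lab][i0:i0 + n].copy() for lab in labs}
    pre = {lab: recording.channels[lab][i0 - n:i0].copy() for lab in labs}
    return SegmentPair(arousal=arousal, pre=pre, fs=fs, event=event)


def preprocess_recording(
    recording: Recording,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    target_fs: float = DEFAULT_TARGET_FS,
) -> Recording:
    """High-pass at the native rate, then resample — the standard chain."""
    return resample(highpass(recording, highpass_hz), target_fs)
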