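"""Automatic arousal-intensity scoring.

The intensity of an arousal is the mean peak-to-peak amplitude of the C3 and
C4 EEG channels within the arousal window. Amplitudes are quantile-binned into
levels 1 (weakest quartile) to 4 (strongest); stable-sleep control windows
("sham arousals") are assigned level 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ArousalEvent, Hypnogram
from .preprocess import SegmentPair

logger = logging.getLogger(__name__)

DEFAULT_SHAM_RANGE = (10, 14)   # sham windows per recording, drawn uniformly
DEFAULT_SHAM_LEN_S = 9.0
DEFAULT_SHAM_CLEARANCE_S = 10.0  # minimum distance from any arousal boundary


@dataclass(frozen=True)
class BinningThresholds:
    """Quartile edges for amplitude binning (volts).

    Levels use right-closed intervals: ``(lower_edge, q1] -> 1``,
    ``(q1, q2] -> 2``, ``(q2, q3] -> 3``, ``(q3, upper_edge] -> 4``.
    The lower edge is an open sentinel slightly below the observed minimum,
    as standard quantile-binning implementations produce.
    """

    lower_edge: float
    q1: float
    q2: float
    q3: float
    upper_edge: float

    def __post_init__(self) -> None:
        edges = (self.lower_edge, self.q1, self.q2, self.q3, self.upper_edge)
        if not all(a < b for a, b in zip(edges, edges[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {edges}")


#: Reference quartile edges from a 96-recording clinical OSA cohort
#: (13,532 arousals). Dataset-specific; the default mode re-fits thresholds
#: on the data at hand instead of applying these.
REFERENCE_THRESHOLDS = BinningThresholds(
    lower_edge=-0.001,
    q1=0.000093,
    q2=0.000164,
    q3=0.000404,
    upper_edge=0.00603,
)


@dataclass(frozen=True)
class ScoredEvent:
    """An event with its measured amplitude and assigned intensity level."""

    event: ArousalEvent
    amplitude: float
    level: int

    def __post_init__(self) -> None:
        if (self.level == 0) != self.event.is_sham:
            raise ValueError("level 0 is reserved for sham events, and vice versa")
        if not self.event.is_sham and self.level not in (1, 2, 3, 4):
            raise ValueError(f"non-sham level must be 1..4, got {self.level}")


def amplitude_distance(pair: SegmentPair) -> float:
    """Mean over {C3, C4} of (max - min) within the arousal window, in volts."""
    for lab in ("C3", "C4"):
        if lab not in pair.arousal:
            raise KeyError(f"segment pair lacks channel {lab}; has {list(pair.arousal)}")
        if len(pair.arousal[lab]) == 0:
            raise ValueError(f"empty arousal segment for channel {lab}")
    return float(np.mean([np.ptp(pair.arousal[lab]) for lab in ("C3", "C4")]))


def fit_quartile_thresholds(amplitudes) -> BinningThresholds:
    """Fit quartile bin edges from observed (non-sham) amplitudes.

    Quantiles use linear interpolation between order statistics. The outer
    edges extend slightly beyond the observed range so every fitted value
    falls inside a bin.
    """
    a = np.asarray(list(amplitudes), dtype=float)
    if len(np.unique(a)) < 8:
        raise ValueError(
            f"need at least 8 distinct amplitudes to fit quartiles, got {len(np.unique(a))}"
        )
    q1, q2, q3 = np.quantile(a, [0.25, 0.5, 0.75], method="linear")
    amin, amax = float(a.min()), float(a.max())
    span = amax - amin
    return BinningThresholds(
        lower_edge=amin - 1e-3 * span,
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        upper_edge=amax,
    )


def assign_level(amplitude: float, thresholds: BinningThresholds, is_sham: bool = False) -> int:
    """Map an amplitude to an intensity level 0-4.

    Sham events are level 0 by definition. Amplitudes beyond the outer edges
    clamp to levels 1 or 4 with a warning (they can occur when thresholds are
    fitted on one dataset and applied to another).
    """
    if is_sham:
        return 0
    if amplitude < 0:
        raise ValueError(f"a peak-to-peak amplitude cannot be negative: {amplitude}")
    if amplitude <= thresholds.lower_edge:
        logger.warning("amplitude %.3g V below lower edge; clamping to level 1", amplitude)
        return 1
    if amplitude > thresholds.upper_edge:
        logger.warning("amplitude %.3g V above upper edge; clamping to level 4", amplitude)
        return 4
    # right-closed bins: level = 1 + #{q : amplitude > q}
    return 1 + int(sum(amplitude > q for q in (thresholds.q1, thresholds.q2, thresholds.q3)))


def select_sham_windows(
    hypnogram: Hypnogram,
    events: list[ArousalEvent],
    rng: np.random.Generator,
    n_range: tuple[int, int] = DEFAULT_SHAM_RANGE,
    length_s: float = DEFAULT_SHAM_LEN_S,
    clearance_s: float = DEFAULT_SHAM_CLEARANCE_S,
) -> list[ArousalEvent]:
    """Pick stable-sleep control windows for one recording.

    Draws a target count uniformly in ``n_range`` (inclusive) and places that
    many non-overlapping windows of ``length_s`` seconds, each entirely within
    non-wake epochs and at least ``clearance_s`` away from every arousal
    boundary. The window's own pre-window (used later for feature
    normalization) must also fit inside stable sleep, so candidates start no
    earlier than ``length_s`` seconds in. Returns fewer windows with a warning
    when eligible sleep is scarce.
    """
    lo, hi = n_range
    target = int(rng.integers(lo, hi + 1))
    real = [e for e in events if not e.is_sham]

    def eligible(t: float) -> bool:
        if not hypnogram.is_sleep_range(t - length_s, t + length_s):
            return False
        for e in real:
            if t - clearance_s < e.end and e.onset < t + length_s + clearance_s:
                return False
        return True

    # 1-s candidate grid, shuffled; greedy non-overlapping selection.
    candidates = np.arange(length_s, hypnogram.duration - length_s, 1.0)
    candidates = candidates[[eligible(float(t)) for t in candidates]]
    order = rng.permutation(len(candidates))
    chosen: list[float] = []
    for idx in order:
        t = float(candidates[idx])
        if all(abs(t - c) >= length_s for c in chosen):
            chosen.append(t)
            if len(chosen) == target:
                break
    if len(chosen) < target:
        logger.warning(
            "only %d of %d sham windows could be placed (insufficient stable sleep)",
            len(chosen), target,
        )
    return [
        ArousalEvent(
            onset=t,
            duration=length_s,
            stage_at_onset=hypnogram.stage_at(t),
            is_sham=True,
        )
        for t in sorted(chosen)
    ]


def score_events(
    events_with_amplitudes: list[tuple[ArousalEvent, float]],
    thresholds: BinningThresholds,
) -> list[ScoredEvent]:
    """Assign a level to every (event, amplitude) pair under one threshold set."""
    return [
        ScoredEvent(event=e, amplitude=a, level=assign_level(a, thresholds, e.is_sham))
        for e, a in events_with_amplitudes
    ]
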