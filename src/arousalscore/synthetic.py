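"""Synthetic polysomnography with recoverable arousal-intensity structure.

Generates multi-channel EEG/EMG with stage-dependent spectral content, a
Markov-chain hypnogram over {W, N1, N2, N3, REM}, and injected arousal events
(additive 8-30 Hz bursts with raised-cosine ramps) whose peak-to-peak scales
follow a log-normal law partitioned into four strata. The ground truth of
every injected event (scale, stratum, stage) is retained so downstream
recovery can be tested. Stands in for restricted clinical recordings; it
emulates the statistical structure the pipeline assumes, not EEG
microstructure (no spindles, K-complexes, or artifacts).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import io as asio
from .io import ArousalEvent, Hypnogram, Recording, STAGES

logger = logging.getLogger(__name__)

BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: Relative band-power weights per stage (normalized internally). N3 is
#: delta-dominated slow-wave sleep; REM is low-voltage mixed-frequency,
#: wake-like; W carries the most alpha/beta.
DEFAULT_STAGE_SPECTRA: dict[str, dict[str, float]] = {
    "W":   {"delta": 0.15, "theta": 0.15, "alpha": 0.40, "beta": 0.30},
    "N1":  {"delta": 0.30, "theta": 0.40, "alpha": 0.20, "beta": 0.10},
    "N2":  {"delta": 0.45, "theta": 0.35, "alpha": 0.12, "beta": 0.08},
    "N3":  {"delta": 0.75, "theta": 0.17, "alpha": 0.05, "beta": 0.03},
    "REM": {"delta": 0.25, "theta": 0.35, "alpha": 0.20, "beta": 0.20},
}

#: 30-s epoch transition probabilities, rows/columns in STAGES order.
#: Chosen so the stationary occupancy approximates a clinical OSA cohort
#: (roughly N1 23%, N2 52%, N3 6%, REM 15%, W 4% of time in bed).
DEFAULT_STAGE_TRANSITION = np.array(
    [
        # W     N1     N2     N3     REM
        [0.60, 0.35, 0.05, 0.00, 0.00],   # W
        [0.06, 0.62, 0.30, 0.00, 0.02],   # N1
        [0.01, 0.08, 0.82, 0.04, 0.05],   # N2
        [0.00, 0.00, 0.25, 0.75, 0.00],   # N3
        [0.02, 0.08, 0.10, 0.00, 0.80],   # REM
    ]
)

EEG_CHANNELS = ("C3", "C4", "O1", "O2", "F3", "F4")
CHIN_BURST_FACTOR = 0.4  # EMG tone rise relative to the EEG burst scale
RAMP_S = 0.5             # raised-cosine on/off ramp of each burst


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the simulated study conditions.

    ``amplitude_law`` is ``(family, params)`` with the log-normal family
    parametrized by its median (volts) and log-space sigma. The four intensity
    strata are the quartile bins of that law; ``class_separation`` compresses
    within-stratum spread around each stratum's geometric median (1 leaves the
    law untouched, large values make the strata essentially disjoint).
    """

    n_recordings: int = 8
    duration: float = 2700.0
    fs: float = 200.0
    seed: int = 0
    stage_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAGE_TRANSITION.copy()
    )
    stage_spectra: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(w) for s, w in DEFAULT_STAGE_SPECTRA.items()}
    )
    arousal_rate: float = 32.0           # events per hour (cohort arousal index)
    amplitude_law: tuple = ("lognormal", {"median": 1.8e-4, "sigma": 0.9})
    class_separation: float = 5.0
    event_duration_range: tuple[float, float] = (3.0, 15.0)
    background_rms: float = 10e-6        # volts, per EEG channel

    def validate(self) -> None:
        t = np.asarray(self.stage_transition, dtype=float)
        if t.shape != (5, 5):
            raise ValueError(f"stage_transition must be 5x5, got {t.shape}")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("stage_transition rows must be non-negative and sum to 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration < 60:
            raise ValueError("duration must be at least 60 s")
        lo, hi = self.event_duration_range
        if lo < 3.0 or hi < lo:
            raise ValueError("event durations must satisfy 3 <= lo <= hi")
        family, params = self.amplitude_law
        if family != "lognormal":
            raise ValueError(f"unsupported amplitude law family {family!r}")
        if params["median"] <= 0 or params["sigma"] <= 0:
            raise ValueError("log-normal law needs positive median and sigma")
        if self.class_separation < 1.0:
            raise ValueError("class_separation must be >= 1")
        for stage in STAGES:
            if stage not in self.stage_spectra:
                raise ValueError(f"stage_spectra lacks stage {stage}")


def sample_hypnogram(config: SyntheticConfig, rng: np.random.Generator) -> Hypnogram:
    """Markov-chain hypnogram in 30-s epochs; the night starts awake."""
    config.validate()
    n_epochs = math.ceil(config.duration / 30.0)
    t = np.asarray(config.stage_transition, dtype=float)
    labels = ["W"]
    state = 0
    for _ in range(n_epochs - 1):
        state = int(rng.choice(5, p=t[state]))
        labels.append(STAGES[state])
    return Hypnogram(labels=labels)


def _draw_amplitude(
    config: SyntheticConfig, rng: np.random.Generator, stratum: int
) -> float:
    """Draw one event scale from the law, conditional on its stratum (1..4).

    The draw is uniform over the stratum's quartile range of the law, then
    compressed towards the stratum's geometric median by 1/class_separation,
    so large separation makes the four strata essentially disjoint while
    separation 1 reproduces the unmodified law.
    """
    _, params = config.amplitude_law
    mu = math.log(params["median"])
    sigma = params["sigma"]
    u = rng.uniform((stratum - 1) / 4.0, stratum / 4.0)
    z = stats.norm.ppf(u)
    m_s = mu + sigma * stats.norm.ppf((2 * stratum - 1) / 8.0)
    log_a = m_s + (mu + sigma * z - m_s) / config.class_separation
    return math.exp(log_a)


def _draw_strata(n: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random stratum sequence (stratified sampling of the law).

    The law's quartile bins are equiprobable, so stratified draws preserve
    the marginal while keeping per-stratum counts within one of each other —
    which is what makes the intensity classes recoverable by quantile
    binning at any dataset size.
    """
    seq = np.tile(np.arange(1, 5), n // 4)
    remainder = rng.permutation(np.arange(1, 5))[: n % 4]  # unbiased partial tile
    return rng.permutation(np.concatenate([seq, remainder]))


def _place_events(
    config: SyntheticConfig, hypnogram: Hypnogram, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping (onset, duration) pairs.

    Every event needs stable (non-wake, event-free) signal for
    max(10 s, its own duration) before onset — the pre-arousal window used
    for normalization — and 10 s of clearance after its end.
    """
    duration = min(config.duration, hypnogram.duration)
    target = int(rng.poisson(config.arousal_rate * duration / 3600.0))
    lo, hi = config.event_duration_range
    accepted: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * max(target, 1)
    while len(accepted) < target and attempts < max_attempts:
        attempts += 1
        d = float(rng.uniform(lo, hi))
        clear_pre = max(10.0, d)
        onset = float(rng.uniform(clear_pre, duration - d - 10.0))
        if not hypnogram.is_sleep_range(onset - clear_pre, onset + d):
            continue
        ok = True
        for o2, d2 in accepted:
            gap2 = max(10.0, d2)
            if onset - clear_pre < o2 + d2 + 10.0 and o2 - gap2 < onset + d + 10.0:
                ok = False
                break
        if ok:
            accepted.append((onset, d))
    if len(accepted) < target:
        logger.warning(
            "placed %d of %d requested arousals (spacing constraints)",
            len(accepted), target,
        )
    return sorted(accepted)


def _stage_indexed_background(
    config: SyntheticConfig, hypnogram: Hypnogram, rng: np.random.Generator, n: int
) -> np.ndarray:
    """One EEG channel of stage-profiled colored noise (volts)."""
    fs = config.fs
    epoch_of_sample = np.minimum(
        (np.arange(n) / (fs * 30.0)).astype(int), len(hypnogram.labels) - 1
    )
    stage_idx = np.array([STAGES.index(s) for s in hypnogram.labels])[epoch_of_sample]
    out = np.zeros(n)
    for b, (lo, hi) in BANDS.items():
        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
        comp = sps.sosfilt(sos, rng.standard_normal(n))
        comp /= max(np.std(comp), 1e-30)
        weights = np.array(
            [
                config.stage_spectra[s][b] / sum(config.stage_spectra[s].values())
                for s in STAGES
            ]
        )
        out += comp * np.sqrt(weights[stage_idx]) * config.background_rms
    # broadband measurement-noise floor (amplifier noise + residual gamma)
    out += 0.1 * config.background_rms * rng.standard_normal(n)
    return out


def _burst(n_samples: int, fs: float, ptp: float, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated 8-30 Hz noise burst with raised-cosine ramps."""
    sos = sps.butter(4, (8.0, 30.0), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n_samples + int(fs)))[int(fs):]
    ramp_frac = min(1.0, 2 * RAMP_S * fs / n_samples)
    x *= sps.windows.tukey(n_samples, alpha=ramp_frac)
    span = np.ptp(x)
    if span <= 0:
        return np.zeros(n_samples)
    return x * (ptp / span)


def generate_recording(
    config: SyntheticConfig,
    hypnogram: Hypnogram,
    rng: np.random.Generator,
    keep_bursts: bool = False,
):
    """Synthesize one recording: signals, arousal annotations, ground truth.

    Returns ``(recording, events, truth)`` — and, with ``keep_bursts``, a
    fourth element mapping event index to its per-channel burst component
    (useful for verifying injected peak-to-peak scales).

    The chin EMG carries broadband 20-70 Hz tone (halved during REM atonia)
    and receives a scaled-down copy of each burst.
    """
    config.validate()
    if hypnogram.duration < config.duration - 1e-9:
        raise ValueError("hypnogram does not cover the configured duration")
    fs = config.fs
    n = int(round(config.duration * fs))

    channels: dict[str, np.ndarray] = {}
    for lab in EEG_CHANNELS:
        channels[lab] = _stage_indexed_background(config, hypnogram, rng, n)
    # chin EMG: high-frequency tone, reduced in REM
    sos = sps.butter(4, (20.0, min(70.0, fs / 2 - 1)), btype="bandpass", fs=fs, output="sos")
    chin = sps.sosfilt(sos, rng.standard_normal(n))
    chin /= max(np.std(chin), 1e-30)
    chin = 0.95 * chin + 0.3 * rng.standard_normal(n)  # broadband floor of real EMG
    epoch_of_sample = np.minimum((np.arange(n) / (fs * 30.0)).astype(int), len(hypnogram.labels) - 1)
    rem_mask = np.array([s == "REM" for s in hypnogram.labels])[epoch_of_sample]
    chin *= np.where(rem_mask, 0.5, 1.0) * (config.background_rms / 2.0)
    channels["chin"] = chin

    placements = _place_events(config, hypnogram, rng)
    strata = _draw_strata(len(placements), rng)
    events: list[ArousalEvent] = []
    truth_rows: list[dict] = []
    bursts: dict[int, dict[str, np.ndarray]] = {}
    for k, (onset, dur) in enumerate(placements):
        stratum = int(strata[k])
        amp = _draw_amplitude(config, rng, stratum)
        i0 = int(round(onset * fs))
        n_e = int(round(dur * fs))
        event_bursts = {}
        for lab in EEG_CHANNELS:
            b = _burst(n_e, fs, amp, rng)
            channels[lab][i0:i0 + n_e] += b
            event_bursts[lab] = b
        b_chin = _burst(n_e, fs, CHIN_BURST_FACTOR * amp, rng)
        channels["chin"][i0:i0 + n_e] += b_chin
        event_bursts["chin"] = b_chin
        if keep_bursts:
            bursts[k] = event_bursts
        stage = hypnogram.stage_at(onset)
        events.append(
            ArousalEvent(onset=onset, duration=dur, stage_at_onset=stage, is_sham=False)
        )
        truth_rows.append(
            {
                "onset_s": onset,
                "duration_s": dur,
                "amplitude_v": amp,
                "stratum": stratum,
                "stage": stage,
            }
        )

    recording = Recording(channels, fs=fs)
    truth = pd.DataFrame(
        truth_rows, columns=["onset_s", "duration_s", "amplitude_v", "stratum", "stage"]
    )
    if keep_bursts:
        return recording, events, truth, bursts
    return recording, events, truth


def simulate_dataset(config: SyntheticConfig, out_dir: str | Path | None = None) -> list[dict]:
    """Generate ``n_recordings`` independent recordings (optionally to disk).

    Per-recording streams are spawned from the configured seed, so a dataset
    is byte-reproducible regardless of how many recordings are consumed.
    Files per recording: ``<name>.edf``, ``<name>_hypnogram.csv``,
    ``<name>_events.csv``, ``<name>_truth.csv``.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_recordings)
    dataset = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        hyp = sample_hypnogram(config, rng)
        rec, events, truth = generate_recording(config, hyp, rng)
        name = f"rec_{r:03d}"
        dataset.append(
            {"name": name, "recording": rec, "hypnogram": hyp, "events": events, "truth": truth}
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            asio.write_recording(rec, out / f"{name}.edf")
            asio.write_hypnogram(hyp, out / f"{name}_hypnogram.csv")
            asio.write_events(events, out / f"{name}_events.csv")
            truth.to_csv(out / f"{name}_truth.csv", index=False)
    return dataset
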