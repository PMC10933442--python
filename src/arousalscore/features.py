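"""Feature extraction: the 136-dimensional pre-arousal-normalized vector.

For each of four signals (C3/4, O1/2, F3/4, chin EMG) a 5-level discrete
wavelet transform (Daubechies-4) yields six coefficient sets D1..D5, A5, from
which 33 statistics are computed: 6 mean powers, 6 MABS (mean absolute
coefficient values), 15 MABS ratios over all unordered set pairs with the
finer set in the numerator, and 6 variances — 132 features in total. Four
auxiliary features on the C3/4 composite (mean band power spectral intensity,
average power, RMS, DFA scaling exponent) complete the 136. Every feature is
the ratio of its value on the arousal window to its value on the equal-length
pre-arousal window.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .intensity import ScoredEvent
from .io import METADATA_COLUMNS, Recording
from .preprocess import SegmentOutOfBounds, SegmentPair, extract_segment_pair

logger = logging.getLogger(__name__)

WAVELET = "db4"
LEVELS = 5
BOUNDARY_MODE = "periodization"
EPS = 1e-12  # denominator floor for normalization ratios

COEFF_SETS = ("D1", "D2", "D3", "D4", "D5", "A5")
FEATURE_SIGNALS = ("C34", "O12", "F34", "chin")

#: Default bands for power spectral intensity, Hz (clipped at Nyquist).
DEFAULT_PSI_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 60.0))

AUX_FEATURES = ("C34_psi", "C34_avgpow", "C34_rms", "C34_dfa")


def _block_names(signal: str) -> list[str]:
    names = [f"{signal}_meanpow_{s}" for s in COEFF_SETS]
    names += [f"{signal}_mabs_{s}" for s in COEFF_SETS]
    names += [
        f"{signal}_mabsratio_{a}_{b}"
        for a, b in itertools.combinations(COEFF_SETS, 2)
    ]
    names += [f"{signal}_var_{s}" for s in COEFF_SETS]
    return names


#: The 132 wavelet feature names, in the fixed documented order.
DWT_FEATURE_NAMES: tuple[str, ...] = tuple(
    name for sig in FEATURE_SIGNALS for name in _block_names(sig)
)
#: All 136 feature names: the wavelet block plus the four auxiliary features.
FEATURE_NAMES: tuple[str, ...] = DWT_FEATURE_NAMES + AUX_FEATURES

assert len(DWT_FEATURE_NAMES) == 132 and len(FEATURE_NAMES) == 136


@dataclass
class WaveletDecomposition:
    """Coefficient sets of a 5-level DWT: details D1..D5, approximation A5."""

    sets: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [s for s in COEFF_SETS if s not in self.sets or len(self.sets[s]) == 0]
        if missing:
            raise ValueError(f"decomposition lacks non-empty set(s) {missing}")


class FeatureComputationError(ValueError):
    """A feature vector could not be computed for an event (it is dropped)."""


def dwt_decompose(segment: np.ndarray) -> WaveletDecomposition:
    """5-level Daubechies-4 DWT with periodization boundary handling.

    Periodization makes the transform orthonormal, so total coefficient
    energy equals signal energy exactly (up to float round-off).
    """
    x = np.asarray(segment, dtype=float)
    min_len = 2 ** LEVELS
    if x.size < min_len:
        raise ValueError(
            f"segment of {x.size} samples too short for a {LEVELS}-level DWT; "
            f"need at least {min_len}"
        )
    coeffs = pywt.wavedec(x, WAVELET, mode=BOUNDARY_MODE, level=LEVELS)
    # wavedec order: [A5, D5, D4, D3, D2, D1]
    names = ("A5", "D5", "D4", "D3", "D2", "D1")
    return WaveletDecomposition(sets={n: c for n, c in zip(names, coeffs)})


def wavelet_feature_block(dec: WaveletDecomposition, signal: str = "C34") -> dict[str, float]:
    """The 33 statistics of one signal's decomposition, in documented order."""
    out: dict[str, float] = {}
    for s in COEFF_SETS:
        out[f"{signal}_meanpow_{s}"] = float(np.mean(dec.sets[s] ** 2))
    mabs = {s: float(np.mean(np.abs(dec.sets[s]))) for s in COEFF_SETS}
    for s in COEFF_SETS:
        out[f"{signal}_mabs_{s}"] = mabs[s]
    for a, b in itertools.combinations(COEFF_SETS, 2):
        denom = mabs[b]
        if denom == 0.0:
            logger.warning("MABS(%s) is zero for %s; epsilon-guarding ratio", b, signal)
            denom = EPS
        out[f"{signal}_mabsratio_{a}_{b}"] = mabs[a] / denom
    for s in COEFF_SETS:
        out[f"{signal}_var_{s}"] = float(np.var(dec.sets[s]))
    return out


def dfa_exponent(series: np.ndarray, min_window: int = 4, n_scales: int = 12) -> float:
    """Detrended fluctuation analysis scaling exponent alpha.

    Integrates the mean-removed series, splits it into non-overlapping
    windows of sizes log-spaced in [min_window, N/4], removes a linear trend
    per window, and returns the least-squares slope of log F(n) against
    log n. Alpha is ~0.5 for white noise and ~1.5 for Brownian-like signals.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4 * min_window:
        raise ValueError(f"need at least {4 * min_window} samples for DFA, got {n}")
    y = np.cumsum(x - x.mean())
    scales = np.unique(
        np.round(np.geomspace(min_window, n // 4, n_scales)).astype(int)
    )
    fluct = np.empty(len(scales))
    for i, s in enumerate(scales):
        k = n // s
        seg = y[: k * s].reshape(k, s).T  # (s, k)
        t = np.arange(s, dtype=float)
        design = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
        resid = seg - design @ coef
        fluct[i] = np.sqrt(np.mean(resid ** 2))
    fluct = np.maximum(fluct, 1e-300)
    alpha = np.polyfit(np.log(scales), np.log(fluct), 1)[0]
    return float(alpha)


def auxiliary_features(
    segment: np.ndarray,
    fs: float,
    psi_bands=DEFAULT_PSI_BANDS,
    signal: str = "C34",
) -> dict[str, float]:
    """PSI, average power, RMS and DFA exponent of one segment."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    nyq = fs / 2.0
    bands = []
    for lo, hi in psi_bands:
        if lo >= nyq:
            raise ValueError(f"PSI band ({lo}, {hi}) Hz lies entirely above Nyquist {nyq} Hz")
        bands.append((lo, min(hi, nyq)))
    freqs, power = sps.periodogram(x, fs=fs)
    psi = float(np.mean([power[(freqs >= lo) & (freqs < hi)].sum() for lo, hi in bands]))
    avgpow = float(np.mean(x ** 2))
    return {
        f"{signal}_psi": psi,
        f"{signal}_avgpow": avgpow,
        f"{signal}_rms": float(np.sqrt(avgpow)),
        f"{signal}_dfa": dfa_exponent(x),
    }


def assemble_normalized_vector(
    pair: SegmentPair,
    psi_bands=DEFAULT_PSI_BANDS,
    normalize_aux: bool = True,
) -> dict[str, float]:
    """Build the full 136-entry feature vector for one segment pair.

    Every feature is value(arousal) / value(pre-arousal); denominators are
    floored at 1e-12 (with a log entry) so the vector is always finite.
    """
    missing = [s for s in FEATURE_SIGNALS if s not in pair.arousal]
    if missing:
        raise FeatureComputationError(
            f"segment pair lacks composite signal(s) {missing}"
        )
    vec: dict[str, float] = {}

    def ratio(name: str, num: float, den: float) -> float:
        if not np.isfinite(num) or not np.isfinite(den):
            raise FeatureComputationError(f"non-finite raw value for {name}")
        if num == 0.0 and den == 0.0:
            return 1.0  # no energy in either window: no change
        # relative guard: wavelet powers are in volts^2 and can be ~1e-25 in
        # bands the signal barely occupies, so the floor must scale with the
        # operands (an absolute floor would wipe out true tiny/tiny ratios)
        floor = EPS * max(abs(num), abs(den))
        if den < floor:
            logger.debug("pre-arousal value of %s below relative epsilon; guarding", name)
            den = floor
        return num / den

    for sig in FEATURE_SIGNALS:
        block_a = wavelet_feature_block(dwt_decompose(pair.arousal[sig]), sig)
        block_p = wavelet_feature_block(dwt_decompose(pair.pre[sig]), sig)
        for name in block_a:
            vec[name] = ratio(name, block_a[name], block_p[name])

    aux_a = auxiliary_features(pair.arousal["C34"], pair.fs, psi_bands)
    aux_p = auxiliary_features(pair.pre["C34"], pair.fs, psi_bands)
    for name in aux_a:
        vec[name] = ratio(name, aux_a[name], aux_p[name]) if normalize_aux else aux_a[name]

    if not all(np.isfinite(v) for v in vec.values()):
        raise FeatureComputationError("non-finite feature after epsilon guard")
    if list(vec) != list(FEATURE_NAMES):
        vec = {name: vec[name] for name in FEATURE_NAMES}
    return vec


def build_feature_matrix(
    recordings: dict[str, Recording],
    scored: dict[str, list[ScoredEvent]],
    psi_bands=DEFAULT_PSI_BANDS,
    normalize_aux: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """One feature row per scorable event across a set of recordings.

    ``recordings`` maps name -> preprocessed composite-signal recording;
    ``scored`` maps the same names to that recording's scored events.
    Events whose windows cannot be extracted or whose features are not
    finite are dropped; the returned drop log lists each with its reason.
    """
    rows: list[dict] = []
    drop_log: list[dict] = []
    for rec_name, events in scored.items():
        rec = recordings[rec_name]
        for se in events:
            event_id = f"{rec_name}:{se.event.onset:.3f}"
            try:
                pair = extract_segment_pair(rec, se.event, list(FEATURE_SIGNALS))
                vec = assemble_normalized_vector(pair, psi_bands, normalize_aux)
            except (SegmentOutOfBounds, FeatureComputationError, ValueError) as exc:
                drop_log.append({"event_id": event_id, "reason": str(exc)})
                logger.info("dropping event %s: %s", event_id, exc)
                continue
            row = {
                "event_id": event_id,
                "recording": rec_name,
                "stage": se.event.stage_at_onset,
                "level": se.level,
                "onset_s": se.event.onset,
                "duration_s": se.event.duration,
            }
            row.update(vec)
            rows.append(row)
    columns = METADATA_COLUMNS + list(FEATURE_NAMES)
    matrix = pd.DataFrame(rows, columns=columns)
    if matrix["event_id"].duplicated().any():
        raise ValueError("duplicate event ids in feature matrix")
    return matrix, drop_log
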