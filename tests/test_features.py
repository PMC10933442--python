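"""Wavelet feature block, DFA, auxiliary features, and vector assembly."""
import itertools

import numpy as np
import pytest

from arousalscore.features import (
    AUX_FEATURES,
    COEFF_SETS,
    DWT_FEATURE_NAMES,
    FEATURE_NAMES,
    FeatureComputationError,
    WaveletDecomposition,
    assemble_normalized_vector,
    auxiliary_features,
    build_feature_matrix,
    dfa_exponent,
    dwt_decompose,
    wavelet_feature_block,
)
from arousalscore.intensity import ScoredEvent
from arousalscore.io import ArousalEvent, Recording
from conftest import make_pair


def test_dwt_zero_input_all_zero():
    dec = dwt_decompose(np.zeros(384))
    for s in COEFF_SETS:
        np.testing.assert_array_equal(dec.sets[s], 0.0)


def test_dwt_energy_conservation_many_signals():
    """Orthogonality of db4 under periodization: coefficient energy = signal energy."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        # periodization is orthogonal when the length divides by 2**levels
        n = 32 * int(rng.integers(12, 64))
        x = rng.standard_normal(n)
        dec = dwt_decompose(x)
        coeff_energy = sum(np.sum(dec.sets[s] ** 2) for s in COEFF_SETS)
        assert abs(coeff_energy - np.sum(x**2)) < 1e-8 * np.sum(x**2)


def test_dwt_48hz_sine_concentrates_in_d1():
    """At fs 128, D1 spans 32-64 Hz, so a 48 Hz tone dominates D1."""
    fs = 128.0
    t = np.arange(640) / fs
    dec = dwt_decompose(np.sin(2 * np.pi * 48 * t))
    mabs = {s: np.mean(np.abs(dec.sets[s])) for s in COEFF_SETS}
    assert max(mabs, key=mabs.get) == "D1"


def test_dwt_too_short_names_minimum():
    with pytest.raises(ValueError, match="at least 32"):
        dwt_decompose(np.zeros(16))


def test_wavelet_block_counts():
    rng = np.random.default_rng(1)
    block = wavelet_feature_block(dwt_decompose(rng.standard_normal(512)), "C34")
    assert len(block) == 33
    assert len(DWT_FEATURE_NAMES) == 132
    assert len(FEATURE_NAMES) == 136


def test_wavelet_block_constant_coefficient_set():
    sets = {s: np.full(8, 2.0) if s == "D3" else np.ones(8) for s in COEFF_SETS}
    block = wavelet_feature_block(WaveletDecomposition(sets=sets), "X")
    assert block["X_mabs_D3"] == 2.0
    assert block["X_meanpow_D3"] == 4.0
    assert block["X_var_D3"] == 0.0


def test_mabs_ratio_enumeration_matches_combinatorial_oracle():
    rng = np.random.default_rng(2)
    dec = dwt_decompose(rng.standard_normal(512))
    block = wavelet_feature_block(dec, "C34")
    mabs = {s: np.mean(np.abs(dec.sets[s])) for s in COEFF_SETS}
    pairs = list(itertools.combinations(COEFF_SETS, 2))
    assert len(pairs) == 15
    for a, b in pairs:
        # finer set (earlier in D1<...<A5 ordering) in the numerator
        assert block[f"C34_mabsratio_{a}_{b}"] == pytest.approx(mabs[a] / mabs[b])


def test_dfa_white_noise_exponent():
    alphas = [
        dfa_exponent(np.random.default_rng(seed).standard_normal(4096))
        for seed in range(20)
    ]
    assert 0.45 < np.mean(alphas) < 0.55


def test_dfa_brownian_exponent():
    alphas = [
        dfa_exponent(np.cumsum(np.random.default_rng(seed).standard_normal(4096)))
        for seed in range(20)
    ]
    assert 1.4 < np.mean(alphas) < 1.6


def test_dfa_too_short():
    with pytest.raises(ValueError, match="at least 16"):
        dfa_exponent(np.zeros(15))


def test_auxiliary_sine_rms():
    fs = 128.0
    t = np.arange(1280) / fs
    aux = auxiliary_features(np.sin(2 * np.pi * 10 * t), fs)
    assert aux["C34_rms"] == pytest.approx(1 / np.sqrt(2), rel=0.01)
    assert len(aux) == 4


def test_auxiliary_constant_power():
    aux = auxiliary_features(np.full(256, 3.0), 128.0)
    assert aux["C34_avgpow"] == pytest.approx(9.0)
    assert aux["C34_rms"] == pytest.approx(3.0)


def test_auxiliary_band_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        auxiliary_features(np.zeros(256), 128.0, psi_bands=((70.0, 90.0),))


def test_assembled_vector_identity_pair(rng):
    seg = {s: rng.standard_normal(512) * 30e-6 for s in ("C34", "O12", "F34", "chin")}
    pair = make_pair({k: v.copy() for k, v in seg.items()}, seg)
    vec = assemble_normalized_vector(pair)
    assert len(vec) == 136
    assert list(vec) == list(FEATURE_NAMES)
    for name, v in vec.items():
        assert v == pytest.approx(1.0, rel=1e-9), name


def test_dwt_features_scale_invariant(composite_pair):
    vec = assemble_normalized_vector(composite_pair)
    k = 7.3
    scaled = make_pair(
        {s: k * x for s, x in composite_pair.arousal.items()},
        {s: k * x for s, x in composite_pair.pre.items()},
    )
    vec2 = assemble_normalized_vector(scaled)
    for name in DWT_FEATURE_NAMES:
        assert vec2[name] == pytest.approx(vec[name], rel=1e-9), name


def test_assemble_requires_composites(rng):
    pair = make_pair({"C3": rng.standard_normal(512)}, {"C3": rng.standard_normal(512)})
    with pytest.raises(FeatureComputationError, match="C34"):
        assemble_normalized_vector(pair)


def _toy_recording_and_events(rng, n_events=10, fs=128.0, dur_s=400.0):
    n = int(dur_s * fs)
    rec = Recording(
        {s: rng.standard_normal(n) * 30e-6 for s in ("C34", "O12", "F34", "chin")},
        fs=fs,
    )
    events = []
    for i in range(n_events):
        ev = ArousalEvent(onset=30.0 + 35.0 * i, duration=5.0, stage_at_onset="N2")
        events.append(ScoredEvent(event=ev, amplitude=1e-4, level=1 + i % 4))
    return rec, events


def test_build_feature_matrix_counts(rng):
    rec, events = _toy_recording_and_events(rng)
    matrix, drops = build_feature_matrix({"r0": rec}, {"r0": events})
    assert len(matrix) == 10 and drops == []
    assert matrix.shape[1] == 136 + 6  # features + metadata


def test_build_feature_matrix_drop_log(rng):
    rec, events = _toy_recording_and_events(rng)
    bad = ScoredEvent(
        event=ArousalEvent(onset=2.0, duration=5.0, stage_at_onset="N2"),
        amplitude=1e-4,
        level=1,
    )
    matrix, drops = build_feature_matrix({"r0": rec}, {"r0": events + [bad]})
    assert len(matrix) == 10
    assert len(drops) == 1 and "pre-window" in drops[0]["reason"]
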