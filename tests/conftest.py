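"""Shared fixtures: small synthetic signals and a reusable mid-size cohort."""

import numpy as np
import pytest

import dysvox
from dysvox import audio_prep

SR = 16000


def harmonic_vowel(f0=120.0, duration=1.0, n_harm=5, sr=SR, amp=1.0):
    """Phase-continuous harmonic signal (vowel-like), peak-normalized later."""
    t = np.arange(int(sr * duration)) / sr
    x = sum((1.0 / k) * np.sin(2 * np.pi * k * f0 * t) for k in range(1, n_harm + 1))
    return amp * x / np.max(np.abs(x))


@pytest.fixture
def vowel_waveform():
    return audio_prep.Waveform(harmonic_vowel(), SR, "vowel")


@pytest.fixture
def noise_vowel_waveform():
    """1 s of noise followed by 1 s of a 120 Hz vowel."""
    rng = np.random.default_rng(0)
    noise = 0.3 * rng.standard_normal(SR)
    x = np.concatenate([noise, harmonic_vowel()])
    return audio_prep.preprocess(x, SR, "noise_vowel")


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects per class with extracted features (fast, reused widely)."""
    waves, labels, profiles = dysvox.synth_cohort(6, seed=101)
    feats = {w.source_id: dysvox.extract_all(w) for w in waves}
    return waves, np.array(labels), feats


@pytest.fixture(scope="session")
def cohort_supervectors():
    """150-subject cohort -> features -> HC-only UBMs (M=4) -> supervectors.

    Session-scoped: built once and shared by the end-to-end evaluation
    tests.  Returns (ids, labels, per-dimension supervector matrices,
    fused matrix).
    """
    import warnings

    from dysvox import adaptation, gmm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        waves, labels, _ = dysvox.synth_cohort(50, seed=20250921)
        feats = {w.source_id: dysvox.extract_all(w) for w in waves}
    y = np.array(labels)
    ids = [w.source_id for w in waves]
    sv = {}
    for dim in ("articulation", "phonation", "prosody"):
        X_hc = np.vstack(
            [feats[i][dim].values for i, l in zip(ids, y) if l == "HC"]
        )
        ubm = gmm.em_fit(X_hc, 4, seed=7)
        sv[dim] = np.array(
            [adaptation.adapt_recording(feats[i][dim].values, ubm).values for i in ids]
        )
    fused = np.hstack([sv[d] for d in ("articulation", "phonation", "prosody")])
    return ids, y, sv, fused
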