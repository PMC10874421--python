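"""Articulation, phonation and prosody feature extractors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dysvox import audio_prep
from dysvox.audio_prep import OnsetSegment, VoicedSegment, Waveform
from dysvox.features import (
    apq_percent,
    articulation_features,
    bark_band_edges,
    bark_band_energies,
    delta_coefficients,
    jitter_percent,
    phonation_features,
    ppq_percent,
    prosody_features,
    shimmer_percent,
)

from conftest import SR, harmonic_vowel


# ---------------------------------------------------------------------------
# Bark band energies
# ---------------------------------------------------------------------------

class TestBark:
    def test_edges_cover_nyquist_contiguously(self):
        edges = bark_band_edges(SR)
        assert len(edges) == 23
        assert edges[0] == 0.0
        assert edges[-1] == SR / 2
        assert np.all(np.diff(edges) > 0)

    def test_all_zero_frame_at_floor(self):
        e = bark_band_energies(np.zeros(640), SR)
        assert np.allclose(e, np.log(1e-10))

    def test_amplitude_doubling_shifts_log_energy(self):
        rng = np.random.default_rng(0)
        frame = rng.standard_normal(640)
        e1 = bark_band_energies(frame, SR)
        e2 = bark_band_energies(2 * frame, SR)
        np.testing.assert_allclose(e2 - e1, np.log(4.0), atol=1e-9)

    def test_tone_lands_in_its_band(self):
        t = np.arange(640) / SR
        tone = np.sin(2 * np.pi * 250 * t)
        e = bark_band_energies(tone, SR)
        edges = bark_band_edges(SR)
        expected_band = np.searchsorted(edges, 250.0, side="right") - 1
        assert np.argmax(e) == expected_band


# ---------------------------------------------------------------------------
# delta coefficients
# ---------------------------------------------------------------------------

class TestDelta:
    def test_constant_rows_zero(self):
        m = np.ones((5, 4)) * 3.3
        assert np.allclose(delta_coefficients(m), 0.0)

    def test_linear_ramp_interior(self):
        c = 0.7
        m = np.outer(np.arange(8) * c, np.ones(3))
        d = delta_coefficients(m)
        np.testing.assert_allclose(d[2:-2], c, atol=1e-12)

    def test_single_row_zero(self):
        assert np.allclose(delta_coefficients(np.ones((1, 6))), 0.0)


# ---------------------------------------------------------------------------
# articulation
# ---------------------------------------------------------------------------

def _make_onset(left: np.ndarray, right: np.ndarray) -> OnsetSegment:
    samples = np.concatenate([left, right])
    assert len(samples) == 1280
    return OnsetSegment(border_sample=640, samples=samples, sample_rate=SR)


class TestArticulation:
    def test_frame_and_column_counts(self):
        rng = np.random.default_rng(1)
        seg = _make_onset(0.3 * rng.standard_normal(640), harmonic_vowel(duration=0.04))
        fm = articulation_features([seg], SR)
        assert fm.values.shape == (3, 58)
        assert fm.column_labels[:22] == [f"bark_{i+1}" for i in range(22)]
        assert fm.column_labels[22:34] == [f"mfcc_{i+1}" for i in range(12)]

    def test_empty_onset_list(self):
        fm = articulation_features([], SR)
        assert fm.values.shape == (0, 58)

    def test_tone_dominates_its_bark_band_in_voiced_half(self):
        t = np.arange(640) / SR
        tone = np.sin(2 * np.pi * 250 * t)
        seg = _make_onset(np.zeros(640), tone)
        fm = articulation_features([seg], SR)
        edges = bark_band_edges(SR)
        expected_band = np.searchsorted(edges, 250.0, side="right") - 1
        # third frame covers the voiced (right) half only
        assert np.argmax(fm.values[2, :22]) == expected_band

    def test_constant_frames_have_zero_deltas(self):
        # identical left and right halves -> all three frames identical
        rng = np.random.default_rng(2)
        half = 0.5 * rng.standard_normal(320)
        x = np.tile(half, 4)
        seg = OnsetSegment(border_sample=640, samples=x, sample_rate=SR)
        fm = articulation_features([seg], SR)
        np.testing.assert_allclose(fm.values[:, 34:], 0.0, atol=1e-9)

    def test_frame_times_advance_by_hop(self):
        rng = np.random.default_rng(3)
        seg = _make_onset(0.3 * rng.standard_normal(640), harmonic_vowel(duration=0.04))
        fm = articulation_features([seg], SR)
        np.testing.assert_allclose(np.diff(fm.frame_times), 0.020, atol=1e-12)


# ---------------------------------------------------------------------------
# perturbation formulas
# ---------------------------------------------------------------------------

class TestPerturbationMeasures:
    def test_jitter_alternating_periods(self):
        periods = np.array([10, 10.2] * 10)  # ms
        assert jitter_percent(periods) == pytest.approx(100 * 0.2 / 10.1, rel=1e-6)

    def test_shimmer_alternating_amplitudes(self):
        amps = np.array([1.1, 0.9] * 10)
        assert shimmer_percent(amps) == pytest.approx(20.0, rel=1e-6)

    def test_constant_sequences_zero(self):
        assert jitter_percent(np.full(20, 8.0)) == 0.0
        assert shimmer_percent(np.full(20, 0.5)) == 0.0
        assert ppq_percent(np.full(20, 8.0)) == 0.0
        assert apq_percent(np.full(20, 0.5)) == 0.0

    def test_ppq_five_point_oracle(self):
        rng = np.random.default_rng(4)
        periods = 8.0 + 0.1 * rng.standard_normal(30)
        devs = [
            abs(periods[i] - periods[i - 2 : i + 3].mean())
            for i in range(2, len(periods) - 2)
        ]
        expected = 100 * np.mean(devs) / periods.mean()
        assert ppq_percent(periods) == pytest.approx(expected, rel=1e-12)

    def test_apq_windowed_variant_with_few_periods(self):
        # 7 amplitudes < 11 points: neighborhood shrinks to all 7
        amps = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98])
        expected = 100 * abs(amps[3] - amps.mean()) / amps.mean()
        assert apq_percent(amps) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(5)
        vals = 5.0 + 0.2 * rng.standard_normal(25)
        assert jitter_percent(k * vals) == pytest.approx(jitter_percent(vals), rel=1e-9)
        assert apq_percent(k * vals) == pytest.approx(apq_percent(vals), rel=1e-9)


# ---------------------------------------------------------------------------
# phonation
# ---------------------------------------------------------------------------

def _voiced_segment_from(x: np.ndarray, f0: float, n_frames: int | None = None):
    """Wrap a signal as a Waveform plus one VoicedSegment with a flat track."""
    w = Waveform(x, SR, "seg")
    nf = n_frames if n_frames is not None else max((len(x) - 640) // 160 + 1, 1)
    seg = VoicedSegment(0, len(x), np.full(nf, f0), SR, start_frame=0)
    return w, seg


class TestPhonation:
    def test_periodic_vowel_near_zero_perturbation(self):
        w, seg = _voiced_segment_from(harmonic_vowel(duration=0.5), 120.0)
        fm = phonation_features([seg], w)
        assert fm.values.shape == (1, 7)
        d_f0, dd_f0, jit, shim, apq, ppq, energy = fm.values[0]
        assert d_f0 == 0.0 and dd_f0 == 0.0  # flat track
        assert jit < 0.2
        assert shim < 0.5
        assert ppq < 0.2
        assert energy < 0.0  # dB of a peak-1 signal

    def test_amplitude_scale_invariance_of_ratios(self):
        x = harmonic_vowel(duration=0.5)
        w1, seg1 = _voiced_segment_from(x, 120.0)
        w2, seg2 = _voiced_segment_from(0.1 * x, 120.0)
        a = phonation_features([seg1], w1).values[0]
        b = phonation_features([seg2], w2).values[0]
        np.testing.assert_allclose(a[2:6], b[2:6], rtol=1e-6)  # jitter..ppq

    def test_segment_without_cycles_dropped(self):
        w, seg = _voiced_segment_from(np.zeros(1600), 120.0)
        with pytest.warns(UserWarning, match="dropped"):
            fm = phonation_features([seg], w)
        assert fm.values.shape == (0, 7)

    def test_df0_columns_reflect_track_derivative(self):
        x = harmonic_vowel(duration=0.5)
        w = Waveform(x, SR, "seg")
        track = np.array([100.0, 102.0, 104.0, 106.0, 108.0])
        seg = VoicedSegment(0, len(x), track, SR)
        fm = phonation_features([seg], w)
        assert fm.values[0, 0] == pytest.approx(2.0)
        assert fm.values[0, 1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# prosody
# ---------------------------------------------------------------------------

class TestProsody:
    def test_degree5_polynomial_track_recovered(self):
        coeffs = np.array([120.0, 15.0, -8.0, 3.0, -2.0, 1.0])  # ascending
        n = 20
        t = np.linspace(0, 1, n)
        track = np.polyval(coeffs[::-1], t)
        x = harmonic_vowel(duration=(n - 1) * 0.010 + 0.040)
        w = Waveform(x, SR, "poly")
        seg = VoicedSegment(0, len(x), track, SR)
        fm = prosody_features([seg], w)
        got = fm.values[0, 1:7]
        np.testing.assert_allclose(got, coeffs, rtol=1e-6)

    def test_duration_column(self):
        x = harmonic_vowel(duration=0.6)
        w = Waveform(x, SR)
        seg = VoicedSegment(0, 9600, np.full(60, 120.0), SR)
        fm = prosody_features([seg], w)
        assert fm.values[0, 0] == pytest.approx(0.6)

    def test_stationary_signal_constant_energy_nodes(self):
        x = harmonic_vowel(duration=1.0)
        w = Waveform(x, SR)
        seg = VoicedSegment(0, len(x), np.full(90, 120.0), SR)
        fm = prosody_features([seg], w)
        nodes = fm.values[0, 7:]
        assert np.ptp(nodes) < 0.5  # dB spread of a stationary tone

    def test_short_segments_dropped(self):
        x = harmonic_vowel(duration=0.2)
        w = Waveform(x, SR)
        seg = VoicedSegment(0, len(x), np.full(5, 120.0), SR)
        fm = prosody_features([seg], w)
        assert fm.values.shape == (0, 13)


# ---------------------------------------------------------------------------
# cross-cutting invariants
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_column_counts_on_cohort(self, small_cohort):
        _, _, feats = small_cohort
        for mats in feats.values():
            assert mats["articulation"].values.shape[1] == 58
            assert mats["phonation"].values.shape[1] == 7
            assert mats["prosody"].values.shape[1] == 13

    def test_time_shift_invariance(self):
        import dysvox

        w = dysvox.synth_utterance(dysvox.hc_profile(seed=42))
        shifted = audio_prep.Waveform(
            np.concatenate([np.zeros(1600), w.samples]), SR, "shifted"
        )
        a = dysvox.extract_all(w)
        b = dysvox.extract_all(shifted)
        for dim in ("articulation", "phonation", "prosody"):
            np.testing.assert_allclose(
                a[dim].values, b[dim].values, rtol=1e-7, atol=1e-7
            )
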