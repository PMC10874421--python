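"""Articulation, phonation and prosody feature extraction.

Three frame/segment-level feature sets describe complementary speech
dimensions affected by dysarthria:

* articulation (D = 58): 22 Bark-scale critical-band energies plus 12 MFCCs
  with first and second derivatives, computed on 40 ms windows shifted by
  20 ms inside each 80 ms onset-transition segment;
* phonation (D = 7): per voiced segment, the mean absolute first and second
  F0 derivatives, jitter, shimmer, the 11-point amplitude perturbation
  quotient (APQ), the 5-point period perturbation quotient (PPQ) and the
  log energy;
* prosody (D = 13): per voiced segment, its duration, six polynomial
  coefficients modeling the F0 contour and six Lagrange node values
  modeling the energy contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.signal import butter, filtfilt

from .audio_prep import OnsetSegment, VoicedSegment, Waveform

ART_WINDOW = 0.040
ART_HOP = 0.020
N_BARK = 22
N_MFCC = 12
N_MEL_FILTERS = 26
LOG_FLOOR = 1e-10

DIMENSION_SIZES = {"articulation": 58, "phonation": 7, "prosody": 13}

PHONATION_COLUMNS = [
    "dF0_abs_mean",
    "ddF0_abs_mean",
    "jitter_pct",
    "shimmer_pct",
    "apq_pct",
    "ppq_pct",
    "log_energy_db",
]

PROSODY_COLUMNS = (
    ["duration_s"]
    + [f"f0_poly_{i}" for i in range(6)]
    + [f"energy_node_{i}" for i in range(6)]
)

ARTICULATION_COLUMNS = (
    [f"bark_{i + 1}" for i in range(N_BARK)]
    + [f"mfcc_{i + 1}" for i in range(N_MFCC)]
    + [f"dmfcc_{i + 1}" for i in range(N_MFCC)]
    + [f"ddmfcc_{i + 1}" for i in range(N_MFCC)]
)


@dataclass
class FeatureMatrix:
    """T x D matrix of frame- or segment-level features for one recording."""

    values: np.ndarray
    dimension_name: str
    column_labels: list[str]
    source_id: str = ""
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        expected = DIMENSION_SIZES.get(self.dimension_name)
        if expected is not None and self.values.shape[1] != expected:
            raise ValueError(
                f"{self.dimension_name} features must have D={expected}, "
                f"got {self.values.shape[1]}"
            )
        if len(self.column_labels) != self.values.shape[1]:
            raise ValueError("column_labels length mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Bark band energies
# ---------------------------------------------------------------------------

def _hz_to_bark(f: np.ndarray) -> np.ndarray:
    # Traunmueller's critical-band rate approximation
    return 26.81 * f / (1960.0 + f) - 0.53


def _bark_to_hz(z: np.ndarray) -> np.ndarray:
    zz = z + 0.53
    return 1960.0 * zz / (26.81 - zz)


def bark_band_edges(sr: int, n_bands: int = N_BARK) -> np.ndarray:
    """Edges (Hz) of ``n_bands`` contiguous Bark-spaced bands on [0, sr/2]."""
    z_lo = _hz_to_bark(np.array(0.0))
    z_hi = _hz_to_bark(np.array(sr / 2.0))
    z_edges = np.linspace(z_lo, z_hi, n_bands + 1)
    edges = _bark_to_hz(z_edges)
    edges[0], edges[-1] = 0.0, sr / 2.0
    return edges


def bark_band_energies(frame: np.ndarray, sr: int, n_bands: int = N_BARK) -> np.ndarray:
    """Log energy in ``n_bands`` Bark-scale critical bands of one window."""
    frame = np.asarray(frame, dtype=np.float64)
    win = np.hanning(len(frame))
    spec = np.abs(np.fft.rfft(frame * win)) ** 2
    freqs = np.fft.rfftfreq(len(frame), 1.0 / sr)
    edges = bark_band_edges(sr, n_bands)
    band = np.searchsorted(edges, freqs, side="right") - 1
    band = np.clip(band, 0, n_bands - 1)
    energies = np.bincount(band, weights=spec, minlength=n_bands)
    return np.log(np.maximum(energies, LOG_FLOOR))


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(sr: int, n_fft: int, n_filters: int = N_MEL_FILTERS) -> np.ndarray:
    n_bins = n_fft // 2 + 1
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sr / 2.0), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sr).astype(int)
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


_FB_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def mfcc_frame(frame: np.ndarray, sr: int, n_coeffs: int = N_MFCC) -> np.ndarray:
    """MFCCs 1..n_coeffs (c0 excluded) of one Hann-windowed frame."""
    frame = np.asarray(frame, dtype=np.float64)
    n_fft = 1 << int(np.ceil(np.log2(len(frame))))
    key = (sr, n_fft, N_MEL_FILTERS)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = _mel_filterbank(sr, n_fft)
    win = np.hanning(len(frame))
    spec = np.abs(np.fft.rfft(frame * win, n_fft)) ** 2
    mel_energy = np.log(np.maximum(_FB_CACHE[key] @ spec, LOG_FLOOR))
    cepstrum = dct(mel_energy, type=2, norm="ortho")
    return cepstrum[1 : n_coeffs + 1]


# ---------------------------------------------------------------------------
# delta coefficients
# ---------------------------------------------------------------------------

def delta_coefficients(m: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-based temporal derivative with edge replication.

    d_t = sum_n n (c_{t+n} - c_{t-n}) / (2 sum_n n^2), n = 1..width.
    A single row (no temporal context) yields zeros; applying the operator
    twice gives the second derivative.
    """
    m = np.atleast_2d(np.asarray(m, dtype=np.float64))
    T = m.shape[0]
    if T == 1:
        return np.zeros_like(m)
    padded = np.vstack([m[:1]] * width + [m] + [m[-1:]] * width)
    denom = 2.0 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(m)
    for n in range(1, width + 1):
        out += n * (padded[width + n : width + n + T] - padded[width - n : width - n + T])
    return out / denom


# ---------------------------------------------------------------------------
# articulation
# ---------------------------------------------------------------------------

def articulation_features(
    onsets: list[OnsetSegment], sr: int = 16000, source_id: str = ""
) -> FeatureMatrix:
    """58 features per 40 ms frame of each onset segment.

    Column order: 22 Bark band energies | 12 MFCC | 12 delta-MFCC |
    12 delta-delta-MFCC.  Deltas are computed within each onset segment.
    """
    n_win = round(ART_WINDOW * sr)
    n_hop = round(ART_HOP * sr)
    rows, times = [], []
    for seg in onsets:
        x = seg.samples
        n_frames = (len(x) - n_win) // n_hop + 1
        bark = np.empty((n_frames, N_BARK))
        mfcc = np.empty((n_frames, N_MFCC))
        for k in range(n_frames):
            fr = x[k * n_hop : k * n_hop + n_win]
            bark[k] = bark_band_energies(fr, sr)
            mfcc[k] = mfcc_frame(fr, sr)
        d1 = delta_coefficients(mfcc)
        d2 = delta_coefficients(d1)
        rows.append(np.hstack([bark, mfcc, d1, d2]))
        start = seg.border_sample - len(x) // 2
        times.append((start + np.arange(n_frames) * n_hop + n_win / 2) / sr)
    if rows:
        values = np.vstack(rows)
        frame_times = np.concatenate(times)
    else:
        values = np.empty((0, 58))
        frame_times = np.empty(0)
    return FeatureMatrix(values, "articulation", ARTICULATION_COLUMNS, source_id, frame_times)


# ---------------------------------------------------------------------------
# perturbation measures (period/amplitude sequences)
# ---------------------------------------------------------------------------

def jitter_percent(periods: np.ndarray) -> float:
    """Mean absolute consecutive period difference over the mean period, in %."""
    periods = np.asarray(periods, dtype=np.float64)
    if len(periods) < 2:
        return 0.0
    return 100.0 * np.mean(np.abs(np.diff(periods))) / np.mean(periods)


def shimmer_percent(amplitudes: np.ndarray) -> float:
    """Mean absolute consecutive amplitude difference over the mean amplitude, %."""
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if len(amplitudes) < 2:
        return 0.0
    return 100.0 * np.mean(np.abs(np.diff(amplitudes))) / np.mean(amplitudes)


def _perturbation_quotient(values: np.ndarray, points: int) -> float:
    """k-point perturbation quotient: each value against the mean of its
    (points-1)/2-neighborhood including itself, normalized by the overall mean.

    With fewer values than ``points`` the neighborhood shrinks to all
    available values (windowed variant)."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 2:
        return 0.0
    k = min(points, n)
    half = (k - 1) // 2
    devs = []
    for i in range(half, n - (k - 1 - half)):
        neigh = values[i - half : i - half + k]
        devs.append(abs(values[i] - neigh.mean()))
    if not devs:
        return 0.0
    return 100.0 * float(np.mean(devs)) / float(np.mean(values))


def ppq_percent(periods: np.ndarray, points: int = 5) -> float:
    """Five-point period perturbation quotient, in %."""
    return _perturbation_quotient(periods, points)


def apq_percent(amplitudes: np.ndarray, points: int = 11) -> float:
    """Eleven-point amplitude perturbation quotient, in %."""
    return _perturbation_quotient(amplitudes, points)


# ---------------------------------------------------------------------------
# cycle detection
# ---------------------------------------------------------------------------

def detect_cycles(
    x: np.ndarray, sr: int, f0_hint: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle periods (s) and per-cycle peak amplitudes of a voiced stretch.

    Cycle marks are the positive-going zero crossings of the mean-removed
    signal lowpass-filtered just above the expected fundamental; crossings
    are kept only if their spacing is within [0.6, 1.6] of the expected
    period, which rejects spurious marks from residual harmonics.
    """
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    if f0_hint <= 0 or len(x) < round(2 * sr / f0_hint):
        return np.empty(0), np.empty(0)
    fc = min(1.5 * f0_hint, 0.45 * sr)
    b, a = butter(4, fc / (sr / 2), btype="low")
    try:
        y = filtfilt(b, a, x)
    except ValueError:
        return np.empty(0), np.empty(0)
    sign = y > 0
    idx = np.nonzero(~sign[:-1] & sign[1:])[0]
    if len(idx) < 3:
        return np.empty(0), np.empty(0)
    # sub-sample crossing positions by linear interpolation
    frac = -y[idx] / (y[idx + 1] - y[idx])
    marks = idx + frac
    t_exp = sr / f0_hint
    periods, amps, last = [], [], marks[0]
    for m in marks[1:]:
        gap = m - last
        if 0.6 * t_exp <= gap <= 1.6 * t_exp:
            periods.append(gap / sr)
            lo, hi = int(np.ceil(last)), min(int(np.ceil(m)), len(x))
            amps.append(np.max(np.abs(x[lo:hi])) if hi > lo else 0.0)
            last = m
        elif gap > 1.6 * t_exp:
            last = m  # resynchronize after a dropout
    return np.asarray(periods), np.asarray(amps)


# ---------------------------------------------------------------------------
# phonation
# ---------------------------------------------------------------------------

def phonation_features(
    voiced: list[VoicedSegment],
    w: Waveform,
    min_periods: int = 5,
    source_id: str = "",
) -> FeatureMatrix:
    """One 7-vector per voiced segment.

    Columns: mean |dF0|, mean |ddF0| (Hz per frame step), jitter %, shimmer %,
    APQ %, PPQ %, segment log energy (dB).  Segments with fewer than
    ``min_periods`` detected glottal cycles are dropped with a warning;
    segments with 5-10 cycles use the windowed APQ variant.
    """
    rows = []
    dropped = 0
    for seg in voiced:
        x = w.samples[seg.start_sample : seg.end_sample]
        f0 = seg.f0_track
        f0_hint = float(np.median(f0[f0 > 0])) if np.any(f0 > 0) else 0.0
        periods, amps = detect_cycles(x, w.sample_rate, f0_hint)
        if len(periods) < min_periods:
            dropped += 1
            continue
        d1 = np.abs(np.diff(f0))
        d2 = np.abs(np.diff(f0, n=2))
        energy = 10.0 * np.log10(np.mean(x**2) + LOG_FLOOR)
        rows.append(
            [
                float(d1.mean()) if d1.size else 0.0,
                float(d2.mean()) if d2.size else 0.0,
                jitter_percent(periods),
                shimmer_percent(amps),
                apq_percent(amps),
                ppq_percent(periods),
                energy,
            ]
        )
    if dropped:
        warnings.warn(
            f"phonation: dropped {dropped} segment(s) with <{min_periods} cycles "
            f"({source_id!r})",
            stacklevel=2,
        )
    values = np.asarray(rows, dtype=np.float64) if rows else np.empty((0, 7))
    return FeatureMatrix(values, "phonation", PHONATION_COLUMNS, source_id)


# ---------------------------------------------------------------------------
# prosody
# ---------------------------------------------------------------------------

def _frame_energies_db(seg: VoicedSegment, w: Waveform) -> np.ndarray:
    """Short-time log energy (dB) on the segment's contour frame grid."""
    n_hop = round(0.010 * w.sample_rate)
    n_win = round(0.040 * w.sample_rate)
    out = np.empty(seg.n_frames)
    for j in range(seg.n_frames):
        start = (seg.start_frame + j) * n_hop
        fr = w.samples[start : start + n_win]
        out[j] = 10.0 * np.log10(np.mean(fr**2) + LOG_FLOOR) if fr.size else -100.0
    return out


def prosody_features(
    voiced: list[VoicedSegment],
    w: Waveform,
    min_frames: int = 6,
    source_id: str = "",
) -> FeatureMatrix:
    """One 13-vector per voiced segment with at least ``min_frames`` frames.

    Columns: duration (s); six coefficients (ascending powers, time
    normalized to [0, 1]) of a least-squares degree-5 fit to the F0 contour;
    six values of the frame-energy contour at equally spaced nodes — the
    node values are the coefficients of the degree-5 Lagrange interpolant.
    """
    rows = []
    for seg in voiced:
        if seg.n_frames < min_frames:
            continue
        f0 = seg.f0_track
        t = np.linspace(0.0, 1.0, seg.n_frames)
        if seg.n_frames == 6:
            coeffs = np.polyfit(t, f0, 5)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                coeffs = np.polyfit(t, f0, 5)
        f0_coeffs = coeffs[::-1]  # ascending powers
        energies = _frame_energies_db(seg, w)
        nodes = np.linspace(0.0, 1.0, 6)
        energy_nodes = np.interp(nodes, t, energies)
        rows.append(np.concatenate([[seg.duration], f0_coeffs, energy_nodes]))
    values = np.asarray(rows, dtype=np.float64) if rows else np.empty((0, 13))
    return FeatureMatrix(values, "prosody", PROSODY_COLUMNS, source_id)


# ---------------------------------------------------------------------------
# convenience: full per-recording extraction
# ---------------------------------------------------------------------------

def extract_all(
    w: Waveform,
    fmin: float = 60.0,
    fmax: float = 400.0,
    voicing_threshold: float = 0.45,
) -> dict[str, FeatureMatrix]:
    """Segment one recording and extract all three feature dimensions."""
    from . import audio_prep

    contour = audio_prep.estimate_f0(
        w, fmin=fmin, fmax=fmax, voicing_threshold=voicing_threshold
    )
    voiced = audio_prep.voiced_segments(contour, w)
    onsets = audio_prep.onset_segments(contour, w)
    return {
        "articulation": articulation_features(onsets, w.sample_rate, w.source_id),
        "phonation": phonation_features(voiced, w, source_id=w.source_id),
        "prosody": prosody_features(voiced, w, source_id=w.source_id),
    }
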