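"""Loading, preprocessing and voiced/onset segmentation of speech signals.

The pipeline operates on mono 16 kHz audio.  Preprocessing removes the DC
offset and normalizes the peak amplitude to 1.  Segmentation is driven by an
autocorrelation F0 contour: voiced segments are maximal runs of voiced
frames, and onset segments are 80 ms windows centered on each
unvoiced-to-voiced border (40 ms unvoiced to the left, 40 ms voiced to the
right).  Voiced-to-unvoiced transitions (offsets) are deliberately not
extracted.
"""

from __future__ import annotations

import csv
import wave
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_SR = 16000

#: default F0 analysis parameters (adult speech)
F0_MIN = 60.0
F0_MAX = 400.0
FRAME_LEN = 0.040
HOP = 0.010
VOICING_THRESHOLD = 0.45
SILENCE_THRESHOLD = 0.03  # frame peak relative to global peak
MIN_VOICED_DURATION = 0.040
ONSET_HALF = 0.040


class AudioInputError(ValueError):
    """Raised for unreadable, empty or dimensionally invalid audio input."""


@dataclass
class Waveform:
    """Mono audio signal with samples in [-1, 1] after preprocessing."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""
    is_silent: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise AudioInputError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class F0Contour:
    """Frame-level fundamental frequency track; f0 == 0 marks unvoiced frames."""

    frame_times: np.ndarray
    f0: np.ndarray
    frame_len: float = FRAME_LEN
    hop: float = HOP

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        if np.any(self.f0 < 0):
            raise ValueError("f0 values must be nonnegative")


@dataclass
class VoicedSegment:
    """A maximal voiced run, as a half-open sample interval with its f0 track."""

    start_sample: int
    end_sample: int
    f0_track: np.ndarray
    sample_rate: int = TARGET_SR
    start_frame: int = 0  # index of first voiced frame in the source contour

    @property
    def duration(self) -> float:
        return (self.end_sample - self.start_sample) / self.sample_rate

    @property
    def n_frames(self) -> int:
        return len(self.f0_track)


@dataclass
class OnsetSegment:
    """80 ms of signal centered on an unvoiced-to-voiced border."""

    border_sample: int
    samples: np.ndarray
    sample_rate: int = TARGET_SR

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = round(2 * ONSET_HALF * self.sample_rate)
        if len(self.samples) != expected:
            raise ValueError(
                f"onset segment must hold {expected} samples, got {len(self.samples)}"
            )


# ---------------------------------------------------------------------------
# loading and preprocessing
# ---------------------------------------------------------------------------

def _read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a WAV file as float64.  Handles PCM 16/32-bit and float via scipy
    and falls back to a manual decode for 24-bit PCM, which scipy rejects."""
    path = Path(path)
    if not path.exists():
        raise AudioInputError(f"audio file not found: {path}")
    try:
        sr, data = wavfile.read(path)
    except ValueError:
        sr, data = _read_wav_24bit(path)
    data = np.asarray(data)
    if data.size == 0:
        raise AudioInputError(f"empty audio file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:  # downmix channels
        data = data.mean(axis=1)
    return sr, data


def _read_wav_24bit(path: Path) -> tuple[int, np.ndarray]:
    with wave.open(str(path), "rb") as fh:
        if fh.getsampwidth() != 3:
            raise AudioInputError(f"unsupported WAV encoding: {path}")
        sr = fh.getframerate()
        n_ch = fh.getnchannels()
        raw = fh.readframes(fh.getnframes())
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
    vals = (
        b[:, 0].astype(np.int32)
        | (b[:, 1].astype(np.int32) << 8)
        | (b[:, 2].astype(np.int32) << 16)
    )
    vals = np.where(vals >= 1 << 23, vals - (1 << 24), vals)
    data = vals.astype(np.float64) / float((1 << 23) - 1)
    if n_ch > 1:
        data = data.reshape(-1, n_ch)
    return sr, data


def preprocess(
    samples: np.ndarray, sample_rate: int, source_id: str = ""
) -> Waveform:
    """Resample to 16 kHz, remove the DC offset and peak-normalize.

    An all-zero signal is returned unchanged (resampled) with ``is_silent``
    set, so downstream code can skip it without a division by zero.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise AudioInputError("expected a mono signal")
    if sample_rate != TARGET_SR:
        ratio = Fraction(TARGET_SR, int(sample_rate))
        samples = resample_poly(samples, ratio.numerator, ratio.denominator)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak == 0.0:
        warnings.warn(f"all-zero signal: {source_id!r}", stacklevel=2)
        return Waveform(samples, TARGET_SR, source_id, is_silent=True)
    samples = samples - samples.mean()
    samples = samples / np.max(np.abs(samples))
    return Waveform(samples, TARGET_SR, source_id)


def load_and_preprocess(path: str | Path, source_id: str | None = None) -> Waveform:
    """Read a WAV file, downmix to mono and apply :func:`preprocess`."""
    sr, data = _read_wav(path)
    sid = source_id if source_id is not None else Path(path).stem
    return preprocess(data, sr, sid)


# ---------------------------------------------------------------------------
# F0 estimation (Praat-style autocorrelation)
# ---------------------------------------------------------------------------

def estimate_f0(
    w: Waveform,
    fmin: float = F0_MIN,
    fmax: float = F0_MAX,
    frame_len: float = FRAME_LEN,
    hop: float = HOP,
    voicing_threshold: float = VOICING_THRESHOLD,
    silence_threshold: float = SILENCE_THRESHOLD,
) -> F0Contour:
    """Autocorrelation pitch tracking with parabolic peak interpolation.

    Each 40 ms frame is mean-removed, Hann-windowed and autocorrelated via
    the FFT; the normalized autocorrelation is divided by the window's own
    autocorrelation (the lag-domain correction Praat applies) before peak
    picking in the [1/fmax, 1/fmin] lag range.  Frames whose corrected peak
    falls below ``voicing_threshold``, or whose peak amplitude falls below
    ``silence_threshold`` times the global peak, are unvoiced (f0 = 0).
    """
    sr = w.sample_rate
    if not (0 < fmin < fmax < sr / 2):
        raise ValueError("require 0 < fmin < fmax < sr/2")
    n_frame = round(frame_len * sr)
    n_hop = round(hop * sr)
    x = w.samples
    if len(x) < n_frame:
        return F0Contour(np.empty(0), np.empty(0), frame_len, hop)

    n_frames = 1 + (len(x) - n_frame) // n_hop
    starts = np.arange(n_frames) * n_hop
    idx = starts[:, None] + np.arange(n_frame)[None, :]
    frames = x[idx]
    quiet = np.max(np.abs(frames), axis=1) < silence_threshold * np.max(np.abs(x))
    frames = frames - frames.mean(axis=1, keepdims=True)

    win = np.hanning(n_frame)
    nfft = 1 << int(np.ceil(np.log2(2 * n_frame)))
    spec = np.fft.rfft(frames * win, nfft)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft)[:, :n_frame]
    # window autocorrelation for lag-domain normalization
    wspec = np.fft.rfft(win, nfft)
    wac = np.fft.irfft(np.abs(wspec) ** 2, nfft)[:n_frame]
    wac = wac / wac[0]

    r0 = ac[:, 0].copy()
    silent = (r0 <= 0) | quiet
    r0[silent] = 1.0
    r = ac / r0[:, None]
    valid = wac > 0.1  # avoid blow-up near the window edge
    rn = np.where(valid[None, :], r / np.maximum(wac, 0.1)[None, :], 0.0)

    lag_min = int(np.floor(sr / fmax))
    lag_max = int(np.ceil(sr / fmin))
    lag_max = min(lag_max, n_frame - 2)

    f0 = np.zeros(n_frames)
    search = rn[:, lag_min : lag_max + 1]
    best = np.argmax(search, axis=1) + lag_min
    for t in range(n_frames):
        if silent[t]:
            continue
        k = best[t]
        strength = rn[t, k]
        if strength < voicing_threshold:
            continue
        # parabolic interpolation around the peak
        if 1 <= k < n_frame - 1:
            ym1, y0, yp1 = rn[t, k - 1], rn[t, k], rn[t, k + 1]
            denom = ym1 - 2 * y0 + yp1
            delta = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0[t] = float(np.clip(sr / (k + delta), fmin, fmax))

    times = (starts + n_frame / 2) / sr
    return F0Contour(times, f0, frame_len, hop)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _voiced_runs(f0: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of voiced frames as (first_frame, last_frame) inclusive."""
    voiced = f0 > 0
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(voiced) - 1))
    return runs


def voiced_segments(
    c: F0Contour,
    w: Waveform,
    min_duration: float = MIN_VOICED_DURATION,
) -> list[VoicedSegment]:
    """Map maximal voiced frame runs to sample intervals.

    A run spanning frames [a, b] covers samples [a*hop, b*hop + frame_len),
    so even a single voiced frame yields a 40 ms segment; runs whose sample
    span falls below ``min_duration`` are discarded.
    """
    sr = w.sample_rate
    n_hop = round(c.hop * sr)
    n_frame = round(c.frame_len * sr)
    n = len(w.samples)
    out = []
    for a, b in _voiced_runs(c.f0):
        start = a * n_hop
        end = min(b * n_hop + n_frame, n)
        if end - start < round(min_duration * sr):
            continue
        out.append(
            VoicedSegment(start, end, c.f0[a : b + 1].copy(), sr, start_frame=a)
        )
    return out


def onset_segments(
    c: F0Contour,
    w: Waveform,
    min_duration: float = MIN_VOICED_DURATION,
    half: float = ONSET_HALF,
) -> list[OnsetSegment]:
    """Extract 80 ms unvoiced-to-voiced transition segments.

    One segment per retained voiced run whose first frame is preceded by at
    least 40 ms of unvoiced frames; borders closer than 40 ms to either
    signal edge are dropped rather than zero-padded.  Voiced-to-unvoiced
    offsets are never extracted.
    """
    sr = w.sample_rate
    n_hop = round(c.hop * sr)
    n_half = round(half * sr)
    guard = int(np.ceil(n_half / n_hop))  # frames covering the left half
    n = len(w.samples)
    out = []
    for seg in voiced_segments(c, w, min_duration):
        a = seg.start_frame
        if a < guard:
            continue  # border at/near the signal start
        if np.any(c.f0[a - guard : a] > 0):
            continue  # left half not fully unvoiced
        border = a * n_hop
        if border - n_half < 0 or border + n_half > n:
            continue
        out.append(OnsetSegment(border, w.samples[border - n_half : border + n_half], sr))
    return out


def write_segment_table(
    path: str | Path,
    source_id: str,
    voiced: list[VoicedSegment],
    onsets: list[OnsetSegment],
) -> None:
    """Persist segment boundaries as a CSV table."""
    n_half = None
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "kind", "start_sample", "end_sample"])
        for seg in voiced:
            writer.writerow([source_id, "voiced", seg.start_sample, seg.end_sample])
        for seg in onsets:
            n_half = len(seg.samples) // 2
            writer.writerow(
                [source_id, "onset", seg.border_sample - n_half, seg.border_sample + n_half]
            )
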