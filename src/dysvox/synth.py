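"""Synthetic utterance and cohort generation.

The clinical recordings this pipeline targets are access-restricted, so all
testing and calibration run on a source-filter-lite generator: utterances
alternate bandpassed noise bursts (plosive-like unvoiced onsets) with
harmonic voiced nuclei synthesized cycle by cycle, which gives exact control
over the period and amplitude sequences that the perturbation measures
(jitter, shimmer, APQ, PPQ) read out.

Three class profiles mirror the clinical phenomenology the features are
meant to capture:

* healthy-control-like: moderate F0 drift, fast voicing onsets, low cycle
  perturbation;
* hypokinetic (Parkinson-like): compressed F0 range, slow/soft voicing
  onsets, reduced loudness, raised jitter (monopitch, weak onset energy);
* hyperkinetic (essential-tremor-like): 4-8 Hz modulation of F0 and
  amplitude (vocal tremor) with a wide F0 range.

The generator does not attempt perceptually realistic speech — no vocal
tract resonances beyond a fixed harmonic rolloff, no phonotactics — it only
reproduces the segmental and cycle-level statistics the feature extractors
and the GMM-UBM stack consume.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.signal import butter, lfilter

from . import audio_prep
from .audio_prep import Waveform
from .gmm import GMMParams

CLASS_TAGS = ("HC", "PD", "ET")


@dataclass
class SynthProfile:
    """Parameters of one synthetic speaker class (or one subject)."""

    class_tag: str = "HC"
    base_f0: float = 130.0  # Hz, median fundamental
    f0_range: float = 30.0  # Hz, slow per-syllable drift span
    tremor_rate: float = 0.0  # Hz, 4-8 for the hyperkinetic profile
    tremor_depth: float = 0.0  # fraction of base_f0
    amplitude_mod_depth: float = 0.02  # fraction, at tremor_rate (or 3 Hz)
    onset_rise_time: float = 0.010  # s, voicing onset ramp (long = soft onset)
    jitter_inject: float = 0.5  # %, sd of cycle-level period perturbation
    shimmer_inject: float = 2.0  # %, sd of cycle-level amplitude perturbation
    voiced_level: float = 1.0  # relative voiced amplitude
    n_syllables: int = 6
    syllable_ms: float = 200.0  # voiced nucleus duration
    burst_ms: float = 100.0  # unvoiced burst duration
    gap_ms: float = 60.0  # silence between syllables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tremor_rate < 0:
            raise ValueError("tremor_rate must be nonnegative")
        if not (0 <= self.tremor_depth <= 0.5 and 0 <= self.amplitude_mod_depth <= 0.5):
            raise ValueError("modulation depths must lie in [0, 0.5]")
        if min(self.syllable_ms, self.burst_ms, self.gap_ms) <= 0:
            raise ValueError("durations must be positive")


def hc_profile(**overrides) -> SynthProfile:
    """Neutral profile: stable F0, crisp onsets."""
    return SynthProfile(class_tag="HC", **overrides)


def pd_profile(**overrides) -> SynthProfile:
    """Hypokinetic profile: monopitch, soft slow onsets, reduced loudness."""
    defaults = dict(
        class_tag="PD",
        base_f0=125.0,
        f0_range=8.0,
        onset_rise_time=0.060,
        jitter_inject=1.5,
        shimmer_inject=5.0,
        voiced_level=0.55,
        amplitude_mod_depth=0.02,
    )
    defaults.update(overrides)
    return SynthProfile(**defaults)


def et_profile(**overrides) -> SynthProfile:
    """Hyperkinetic profile: 5 Hz F0/amplitude tremor, wide pitch excursions."""
    defaults = dict(
        class_tag="ET",
        base_f0=140.0,
        f0_range=35.0,
        tremor_rate=5.0,
        tremor_depth=0.08,
        amplitude_mod_depth=0.20,
        jitter_inject=1.0,
        shimmer_inject=3.0,
    )
    defaults.update(overrides)
    return SynthProfile(**defaults)


PROFILE_FACTORIES = {"HC": hc_profile, "PD": pd_profile, "ET": et_profile}


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _noise_burst(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    b, a = butter(4, [2000 / (sr / 2), 6000 / (sr / 2)], btype="band")
    noise = lfilter(b, a, noise)
    env = np.hanning(2 * n)[:n] if n > 1 else np.ones(n)
    peak = np.max(np.abs(noise)) or 1.0
    return 0.30 * env * noise / peak


def _voiced_nucleus(
    duration_s: float,
    f0_of_t,
    amp_of_t,
    sr: int,
    rng: np.random.Generator,
    jitter_pct: float,
    shimmer_pct: float,
    t0: float,
) -> np.ndarray:
    """Cycle-by-cycle harmonic synthesis with controlled perturbations.

    Cycle boundaries fall on fractional sample positions and the waveform is
    generated by continuous phase accumulation, so injected jitter is the
    only cycle-length perturbation (integer rounding of periods would
    otherwise alternate between two lengths and create a spurious
    subharmonic)."""
    bounds = [0.0]
    freqs: list[float] = []
    amps: list[float] = []
    t = 0.0
    while t < duration_s:
        f = f0_of_t(t0 + t)
        period = (1.0 / f) * (1.0 + jitter_pct / 100.0 * rng.standard_normal())
        period = max(period, 1.0 / 500.0)
        amp = amp_of_t(t0 + t) * (1.0 + shimmer_pct / 100.0 * rng.standard_normal())
        freqs.append(1.0 / period)
        amps.append(max(amp, 0.05))
        t += period
        bounds.append(t)
    if not freqs:
        return np.zeros(0)
    n = int(round(t * sr))
    s_times = np.arange(n) / sr
    idx = np.clip(np.searchsorted(bounds, s_times, side="right") - 1, 0, len(freqs) - 1)
    f_s = np.asarray(freqs)[idx]
    a_s = np.asarray(amps)[idx]
    phase = 2.0 * np.pi * np.cumsum(f_s) / sr
    k = np.arange(1, 9)  # 8 harmonics: < Nyquist for any f0 <= 400 Hz
    sig = np.sin(phase[:, None] * k[None, :]) @ (1.0 / k)
    return a_s * sig


def synth_utterance(p: SynthProfile, sr: int = 16000) -> Waveform:
    """Render one utterance: (gap, burst, voiced nucleus) x n_syllables + gap.

    Deterministic for a given profile (including its seed).  The returned
    waveform has already been DC-removed and peak-normalized.
    """
    rng = np.random.default_rng(p.seed)
    mod_rate = p.tremor_rate if p.tremor_rate > 0 else 3.0
    phase0 = rng.uniform(0, 2 * np.pi)

    pieces = []
    t_cursor = 0.0

    def push(x: np.ndarray) -> None:
        nonlocal t_cursor
        pieces.append(x)
        t_cursor += len(x) / sr

    for _ in range(p.n_syllables):
        push(np.zeros(int(p.gap_ms / 1000 * sr)))
        push(_noise_burst(int(p.burst_ms / 1000 * sr), sr, rng))
        f0_syl = p.base_f0 + rng.uniform(-0.5, 0.5) * p.f0_range

        def f0_of_t(t, f0_syl=f0_syl):
            return f0_syl * (
                1.0 + p.tremor_depth * np.sin(2 * np.pi * p.tremor_rate * t + phase0)
            )

        def amp_of_t(t):
            return p.voiced_level * (
                1.0 + p.amplitude_mod_depth * np.sin(2 * np.pi * mod_rate * t + phase0)
            )

        nucleus = _voiced_nucleus(
            p.syllable_ms / 1000,
            f0_of_t,
            amp_of_t,
            sr,
            rng,
            p.jitter_inject,
            p.shimmer_inject,
            t_cursor,
        )
        # onset ramp (soft voicing initiation) and a short offset ramp
        n_on = min(int(p.onset_rise_time * sr), len(nucleus))
        if n_on > 1:
            nucleus[:n_on] *= np.linspace(0.0, 1.0, n_on)
        n_off = min(int(0.010 * sr), len(nucleus))
        if n_off > 1:
            nucleus[-n_off:] *= np.linspace(1.0, 0.0, n_off)
        push(nucleus)
    push(np.zeros(int(p.gap_ms / 1000 * sr)))

    samples = np.concatenate(pieces)
    return audio_prep.preprocess(samples, sr, source_id=f"synth_{p.class_tag}_{p.seed}")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _subject_profile(
    template: SynthProfile, rng: np.random.Generator, subject_sd: float, seed: int
) -> SynthProfile:
    """Lognormal subject-level random effects on the template parameters."""

    def jog(v, sd=subject_sd, lo=None, hi=None):
        out = v * np.exp(sd * rng.standard_normal())
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out

    return replace(
        template,
        base_f0=jog(template.base_f0),
        f0_range=jog(template.f0_range),
        tremor_depth=(
            jog(template.tremor_depth, hi=0.5) if template.tremor_depth > 0 else 0.0
        ),
        tremor_rate=(
            jog(template.tremor_rate, lo=4.0, hi=8.0) if template.tremor_rate > 0 else 0.0
        ),
        amplitude_mod_depth=jog(template.amplitude_mod_depth, hi=0.5),
        onset_rise_time=jog(template.onset_rise_time),
        jitter_inject=jog(template.jitter_inject),
        shimmer_inject=jog(template.shimmer_inject),
        voiced_level=jog(template.voiced_level, sd=subject_sd / 2, hi=1.0),
        seed=seed,
    )


def synth_cohort(
    n_per_class: int,
    profiles: dict[str, SynthProfile] | None = None,
    seed: int = 0,
    subject_sd: float = 0.10,
) -> tuple[list[Waveform], list[str], list[SynthProfile]]:
    """Generate a labeled cohort with subject-level random effects.

    Returns (waveforms, class labels, per-subject profiles); everything is
    reproducible from ``seed``.
    """
    if profiles is None:
        profiles = {tag: PROFILE_FACTORIES[tag]() for tag in CLASS_TAGS}
    rng = np.random.default_rng(seed)
    waves, labels, subj_profiles = [], [], []
    for tag in sorted(profiles):
        template = profiles[tag]
        for j in range(n_per_class):
            sp = _subject_profile(
                template, rng, subject_sd, seed=int(rng.integers(0, 2**31 - 1))
            )
            w = synth_utterance(sp)
            w.source_id = f"{tag}_{j:03d}"
            waves.append(w)
            labels.append(tag)
            subj_profiles.append(sp)
    return waves, labels, subj_profiles


def sample_gmm(
    params: GMMParams, T: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw T i.i.d. frames from a diagonal GMM.

    Returns (X, component_labels) so tests can introspect the assignment.
    """
    rng = np.random.default_rng(seed)
    comps = rng.choice(params.M, size=T, p=params.weights)
    X = params.means[comps] + np.sqrt(params.variances[comps]) * rng.standard_normal(
        (T, params.D)
    )
    return X, comps


def profile_dict(p: SynthProfile) -> dict:
    """Flat dict of profile parameters (manifest serialization)."""
    return asdict(p)
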