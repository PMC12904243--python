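"""Synthetic stimuli: tones, clicks, speech-shaped noise, babble, tokens.

Everything the processing chain and the listening-test simulator consume
can be generated here, deterministically from a seed, so the whole
package is testable without any recorded material. The speech-like
tokens are crude source-filter constructions (harmonic voicing with
formant-like peaks, noise bursts, 3-5 Hz syllabic envelope): they mimic
the level statistics and modulation spectrum of speech, not its phonetic
content, and the babble is a sum of such synthetic talkers rather than a
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioSignal

# Default speech-shaped third-octave band levels (dB, arbitrary reference):
# a long-term average speech spectrum, flat through the low mids with the
# usual high-frequency roll-off. A stand-in shape; override via NoiseSpec.
SPEECH_SHAPED_THIRD_OCTAVE = (
    (100, 54.0), (125, 57.0), (160, 60.0), (200, 62.0), (250, 63.0),
    (315, 63.5), (400, 64.0), (500, 63.5), (630, 62.0), (800, 60.5),
    (1000, 59.0), (1250, 57.5), (1600, 55.5), (2000, 53.5), (2500, 51.5),
    (3150, 49.5), (4000, 47.5), (5000, 45.5), (6300, 43.5), (8000, 41.5),
)


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "ssn"  # "ssn" | "babble" | "white"
    reference_spectrum: tuple = SPEECH_SHAPED_THIRD_OCTAVE
    n_talkers: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("ssn", "babble", "white"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.n_talkers < 1:
            raise ValueError("n_talkers must be >= 1")
        spectrum = tuple((float(f), float(l)) for f, l in self.reference_spectrum)
        if not all(np.isfinite(l) for _, l in spectrum):
            raise ValueError("spectrum levels must be finite")
        object.__setattr__(self, "reference_spectrum", spectrum)


def gen_tone(freq: float, duration: float, rate: int = 16_000,
             amplitude: float = 1.0) -> AudioSignal:
    t = np.arange(int(round(duration * rate))) / rate
    return AudioSignal(samples=amplitude * np.sin(2 * np.pi * freq * t), rate=rate)


def gen_click_train(click_rate: float, duration: float, rate: int = 16_000,
                    amplitude: float = 1.0) -> AudioSignal:
    n = int(round(duration * rate))
    x = np.zeros(n)
    idx = np.round(np.arange(0, duration, 1.0 / click_rate) * rate).astype(int)
    x[idx[idx < n]] = amplitude
    return AudioSignal(samples=x, rate=rate)


def _band_edges(center: float) -> tuple:
    return center * 2 ** (-1 / 6), center * 2 ** (1 / 6)


def band_levels_db(audio: AudioSignal, spectrum=SPEECH_SHAPED_THIRD_OCTAVE):
    """Measured third-octave band levels (dB re 1) at the spectrum's centers."""
    spec = np.fft.rfft(audio.samples)
    freqs = np.fft.rfftfreq(len(audio.samples), 1.0 / audio.rate)
    energy = np.abs(spec) ** 2
    out = []
    for center, _ in spectrum:
        lo, hi = _band_edges(center)
        m = (freqs >= lo) & (freqs < hi)
        e = energy[m].sum()
        out.append(10 * np.log10(e) if e > 0 else -np.inf)
    return np.array(out)


def gen_ssn(spec: NoiseSpec, duration: float, rate: int = 16_000) -> AudioSignal:
    """Gaussian noise shaped to the reference third-octave band levels.

    The gain curve is built from the target *band* levels (equal levels in
    two bands mean equal band energies, not equal spectral density), so a
    flat reference yields flat measured third-octave levels. Output is
    normalized to unit RMS.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * rate))
    white = rng.standard_normal(n)
    fx = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    gain = np.zeros_like(freqs)
    table = spec.reference_spectrum
    nyq = rate / 2.0
    for k, (center, level) in enumerate(table):
        lo, hi = _band_edges(center)
        lo_apply = 0.0 if k == 0 else lo
        if lo >= nyq:
            continue
        m = (freqs >= lo_apply) & (freqs < min(hi, nyq))
        # effective bandwidth: part of the band below Nyquist, so bands
        # truncated by the sample rate still carry their full target level
        bw = min(hi, nyq) - lo
        gain[m] = np.sqrt(10 ** (level / 10.0) / bw)
    shaped = np.fft.irfft(fx * gain, n)
    shaped /= np.sqrt(np.mean(shaped**2))
    return AudioSignal(samples=shaped, rate=rate)


def gen_speech_token(seed: int, duration: float, rate: int = 16_000) -> AudioSignal:
    """One synthetic speech-like token: voiced syllables (harmonic source,
    formant-like spectral peaks) alternating with unvoiced bursts and
    silent gaps, under a 3-5 Hz syllabic envelope."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = np.zeros(n)
    f0 = rng.uniform(100.0, 250.0)
    formants = np.array([500.0, 1500.0, 2500.0]) * rng.uniform(0.85, 1.15, 3)
    syllable_rate = rng.uniform(3.0, 5.0)
    t_cursor = 0.0
    while t_cursor < duration:
        syl_dur = rng.uniform(0.6, 1.0) / syllable_rate
        gap = rng.uniform(0.2, 0.5) / syllable_rate
        i0 = int(t_cursor * rate)
        i1 = min(int((t_cursor + syl_dur) * rate), n)
        if i1 <= i0:
            break
        seg_n = i1 - i0
        t = np.arange(seg_n) / rate
        if rng.uniform() < 0.75:  # voiced syllable
            f0_syl = f0 * rng.uniform(0.9, 1.1)
            seg = np.zeros(seg_n)
            h = 1
            while h * f0_syl < min(4000.0, rate / 2):
                fh = h * f0_syl
                # formant-like weighting: resonant peaks over a -6 dB/oct source
                w = sum(1.0 / (1.0 + ((fh - fm) / 200.0) ** 2) for fm in formants)
                seg += (w / h) * np.sin(2 * np.pi * fh * t + rng.uniform(0, 2 * np.pi))
                h += 1
        else:  # unvoiced burst: high-passed noise
            seg = np.diff(rng.standard_normal(seg_n + 1))
        env = np.sin(np.pi * np.arange(seg_n) / seg_n) ** 2  # raised-cosine syllable
        x[i0:i1] += seg * env * rng.uniform(0.5, 1.0)
        t_cursor += syl_dur + gap
    r = np.sqrt(np.mean(x**2))
    if r > 0:
        x /= r
    return AudioSignal(samples=x, rate=rate)


def gen_babble(spec: NoiseSpec, duration: float, rate: int = 16_000) -> AudioSignal:
    """Sum of ``n_talkers`` independent synthetic talkers, unit RMS."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * rate))
    total = np.zeros(n)
    for _ in range(spec.n_talkers):
        talker_seed = int(rng.integers(0, 2**31 - 1))
        total += gen_speech_token(talker_seed, duration, rate).samples
    total /= np.sqrt(np.mean(total**2))
    return AudioSignal(samples=total, rate=rate)


def gen_noise(spec: NoiseSpec, duration: float, rate: int = 16_000) -> AudioSignal:
    if spec.kind == "ssn":
        return gen_ssn(spec, duration, rate)
    if spec.kind == "babble":
        return gen_babble(spec, duration, rate)
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(int(round(duration * rate)))
    return AudioSignal(samples=x / np.sqrt(np.mean(x**2)), rate=rate)


def mix_at_snr(
    speech: AudioSignal, noise: AudioSignal, snr_db: float, seed: int = 0
) -> AudioSignal:
    """Add a random noise segment scaled to sit ``snr_db`` below the speech.

    The speech component is passed through bit-identical (the noise level
    is varied, never the speech); the noise segment is drawn uniformly
    from the noise signal and must be at least as long as the speech.
    """
    if speech.rate != noise.rate:
        raise ValueError("speech and noise sample rates differ")
    ns, nn = len(speech.samples), len(noise.samples)
    if nn < ns:
        raise ValueError("noise shorter than speech")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, nn - ns + 1))
    seg = noise.samples[start:start + ns]
    seg_rms = np.sqrt(np.mean(seg**2))
    if seg_rms == 0:
        raise ValueError("drawn noise segment is silent")
    scale = speech.rms() / seg_rms * 10 ** (-snr_db / 20.0)
    return AudioSignal(samples=speech.samples + scale * seg, rate=speech.rate)
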