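"""Mono audio container and WAV I/O.

All in-package processing uses float64 samples normalized so that full
scale is 1.0 (0 dBFS). Integer PCM files are rescaled on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono pressure waveform.

    Parameters
    ----------
    samples : 1-D float array, full scale = 1.0
    rate : sample rate in Hz
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1:
            raise ValueError(f"audio must be mono (1-D); got shape {s.shape}")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def rms_dbfs(self) -> float:
        r = self.rms()
        if r == 0.0:
            return -np.inf
        return 20.0 * np.log10(r)


def read_wav(path) -> AudioSignal:
    """Read a mono PCM or float WAV file; multichannel input is an error."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"expected mono WAV, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64
        samples = data.astype(np.float64)
    return AudioSignal(samples=samples, rate=int(rate))


def write_wav(path, audio: AudioSignal) -> None:
    """Write float32 WAV (lossless enough for test fixtures)."""
    wavfile.write(path, audio.rate, audio.samples.astype(np.float32))


def resample_to(audio: AudioSignal, rate: int) -> AudioSignal:
    """Polyphase resampling to `rate` (identity if already there)."""
    if audio.rate == rate:
        return audio
    from fractions import Fraction

    from scipy.signal import resample_poly

    frac = Fraction(rate, audio.rate)
    out = resample_poly(audio.samples, frac.numerator, frac.denominator)
    return AudioSignal(samples=out, rate=rate)
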