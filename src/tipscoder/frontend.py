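"""Acoustic front end: calibration, pre-emphasis, filterbank envelopes, LGF.

The chain emulates an envelope-extraction CI coder: the input is RMS-
calibrated, pre-emphasized with a first-order Chebyshev Type II high-pass,
split into band envelopes by a short-time FFT filterbank (128-point Hann,
one frame per stimulation period), and compressed by the loudness-growth
function (LGF) onto normalized channel magnitudes in [0, 1].

No automatic gain control or noise reduction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import cheby2, freqz, lfilter

from .audio import AudioSignal, resample_to
from .pulsecore import ChannelMap

ANALYSIS_RATE = 16_000
NFFT = 128

# 22-band FFT bin allocation at fs 16 kHz, NFFT 128 (bin width 125 Hz):
# bins 2..63 grouped with widths growing toward high frequency, the
# conventional full-array allocation for a 22-electrode device.
BAND_BINS_22 = (1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 4, 4, 5, 5, 6, 7, 8)
_FIRST_BIN = 2


def band_table_22() -> tuple:
    """(lo_hz, hi_hz) edges of the default 22 analysis bands."""
    width = ANALYSIS_RATE / NFFT
    edges = []
    b = _FIRST_BIN
    for n in BAND_BINS_22:
        edges.append(((b - 0.5) * width, (b + n - 0.5) * width))
        b += n
    return tuple(edges)


def band_bins_for_channels(n_channels: int) -> tuple:
    """Group the 22 bands into ``n_channels`` contiguous FFT-bin ranges
    spanning the full frequency range, wider groups at high frequency."""
    if not 1 <= n_channels <= 22:
        raise ValueError("n_channels must be in 1..22")
    base, extra = divmod(22, n_channels)
    sizes = [base] * (n_channels - extra) + [base + 1] * extra
    groups = []
    i = 0
    b = _FIRST_BIN
    for s in sizes:
        n_bins = sum(BAND_BINS_22[i:i + s])
        groups.append((b, b + n_bins))  # half-open bin range
        i += s
        b += n_bins
    return tuple(groups)


@dataclass
class CompressionConfig:
    """Loudness-growth function parameters.

    ``base`` and ``saturation`` bound the acoustic input range mapped onto
    the electrical dynamic range; ``rho`` sets the log-compression
    steepness. ``clips`` counts out-of-range inputs seen so far.
    """

    base: float = 0.0
    saturation: float = 0.39
    rho: float = 416.2
    clips: int = 0

    def __post_init__(self):
        if self.saturation <= self.base:
            raise ValueError("saturation must exceed base")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass(frozen=True)
class EnvelopeFrameSeries:
    """Channel x frame matrix of non-negative band envelopes.

    Rows are ordered low-to-high analysis band; ``electrodes`` gives the
    electrode assigned to each row (apical electrodes carry low bands).
    ``frame_rate`` equals the map's per-channel stimulation rate.
    """

    values: np.ndarray
    frame_rate: float
    band_table: tuple
    electrodes: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be channels x frames")
        if np.any(v < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def normalize_rms(audio: AudioSignal, target_dbfs: float = -20.0) -> AudioSignal:
    """Scale the signal so its RMS sits at ``target_dbfs`` re full scale."""
    r = audio.rms()
    if r == 0.0:
        raise ValueError("cannot normalize silence")
    target = 10.0 ** (target_dbfs / 20.0)
    return AudioSignal(samples=audio.samples * (target / r), rate=audio.rate)


def preemph_coeffs(
    fs: float = ANALYSIS_RATE, stop_hz: float = 4000.0, stop_atten_db: float = 3.0
):
    """First-order Chebyshev Type II high-pass design (b, a)."""
    if not 0 < stop_hz < fs / 2:
        raise ValueError("stopband edge must lie strictly below Nyquist")
    return cheby2(1, stop_atten_db, stop_hz, btype="highpass", fs=fs)


def pre_emphasize(
    audio: AudioSignal, stop_hz: float = 4000.0, stop_atten_db: float = 3.0
) -> AudioSignal:
    """High-pass pre-emphasis boosting high frequencies before analysis."""
    if audio.rate < ANALYSIS_RATE:
        raise ValueError("sample rate must be >= 16 kHz for pre-emphasis")
    b, a = preemph_coeffs(audio.rate, stop_hz, stop_atten_db)
    return AudioSignal(samples=lfilter(b, a, audio.samples), rate=audio.rate)


def preemph_response(freqs_hz, fs: float = ANALYSIS_RATE, **kw):
    """Complex frequency response of the pre-emphasis filter at ``freqs_hz``."""
    b, a = preemph_coeffs(fs, **kw)
    _, h = freqz(b, a, worN=np.atleast_1d(freqs_hz), fs=fs)
    return h


def analyze_envelopes(
    audio: AudioSignal, cmap: ChannelMap, preemph: bool = True
) -> EnvelopeFrameSeries:
    """Band envelopes at the per-channel stimulation rate.

    The audio is resampled to 16 kHz, optionally pre-emphasized, and
    analyzed with a 128-point Hann-windowed FFT once per stimulation
    period. Each channel's envelope is the root-power sum of the FFT bins
    in its band, scaled so a unit-amplitude bin-centred sinusoid yields
    an envelope of 1. (A coherent vector sum of the complex bins is not
    usable here: the Hann leakage into the two neighbouring bins is in
    antiphase with the centre bin, so a tone centred inside a band would
    cancel almost completely.)
    """
    audio = resample_to(audio, ANALYSIS_RATE)
    if preemph:
        audio = pre_emphasize(audio)
    x = audio.samples
    if len(x) < NFFT:
        raise ValueError(f"audio shorter than one analysis block ({NFFT} samples)")
    n_ch = cmap.n_channels
    groups = band_bins_for_channels(n_ch)
    rate = cmap.rate
    n_frames = int(round(len(x) / ANALYSIS_RATE * rate))
    win = np.hanning(NFFT + 1)[:NFFT]  # periodic Hann
    # 2/sum(win) normalizes a bin-centred tone's centre bin to its
    # amplitude; sqrt(0.375) is the Hann 3-bin root-power norm
    scale = 2.0 / (win.sum() * np.sqrt(0.375))
    starts = np.round(np.arange(n_frames) * ANALYSIS_RATE / rate).astype(int)
    xpad = np.concatenate([x, np.zeros(NFFT)])
    frames = np.stack([xpad[s:s + NFFT] for s in starts])
    power = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    env = np.empty((n_ch, n_frames))
    for ci, (lo, hi) in enumerate(groups):
        env[ci] = np.sqrt(power[:, lo:hi].sum(axis=1)) * scale
    width = ANALYSIS_RATE / NFFT
    table = tuple(((lo - 0.5) * width, (hi - 0.5) * width) for lo, hi in groups)
    # low band -> most apical active electrode (highest electrode number)
    electrodes = tuple(sorted(cmap.electrodes, reverse=True))
    return EnvelopeFrameSeries(
        values=env, frame_rate=rate, band_table=table, electrodes=electrodes
    )


def compress_lgf(p, cfg: CompressionConfig):
    """Loudness-growth compression onto [0, 1].

    v = log(1 + rho*(p-base)/(sat-base)) / log(1+rho), clipped at both
    ends; inputs above saturation increment the config's clip counter.
    """
    arr = np.asarray(p, dtype=np.float64)
    frac = (arr - cfg.base) / (cfg.saturation - cfg.base)
    over = int(np.count_nonzero(frac > 1.0))
    if over:
        cfg.clips += over
    frac = np.clip(frac, 0.0, 1.0)
    v = np.log1p(cfg.rho * frac) / np.log1p(cfg.rho)
    return float(v) if np.isscalar(p) else v
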