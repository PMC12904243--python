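"""CIS and ACE (N-of-M) pulse-pattern encoders.

CIS stimulates every active channel once per cycle; ACE selects, in each
cycle, the N channels with the largest band amplitude out of the M active
channels and stimulates only those. Both emit interleaved biphasic-pulse
timing: channels fire in the map's within-cycle order, each occupying one
scheduling slot of (2*phase + inter-phase gap + overhead) microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frontend import CompressionConfig, EnvelopeFrameSeries, compress_lgf
from .pulsecore import (
    ChannelMap,
    PulseSequence,
    ValidationError,
    max_channels_per_cycle,
)

__all__ = [
    "StrategyConfig",
    "max_channels_per_cycle",
    "encode_cis",
    "select_maxima",
    "encode_ace",
]


@dataclass(frozen=True)
class StrategyConfig:
    kind: str = "cis"  # "cis" | "ace"
    n_maxima: int | None = None  # ACE only
    cycle_overhead_us: float = 7.0
    emit_zero_slots: bool = True  # keep magnitude-0 timing slots

    def __post_init__(self):
        if self.kind not in ("cis", "ace"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")


def _check_feasible(cmap: ChannelMap, n_active: int) -> None:
    limit = max_channels_per_cycle(
        cmap.rate, cmap.phase_us, cmap.ipg_us, cmap.overhead_us
    )
    if n_active > limit:
        raise ValidationError(
            f"{n_active} channels per cycle infeasible: max_channels_per_cycle"
            f"({cmap.rate}, {cmap.phase_us}, {cmap.ipg_us}, "
            f"{cmap.overhead_us}) = {limit}"
        )


def _emit(env, cmap, selected_per_frame, compression):
    """Shared pulse emission: one slot per selected channel per frame."""
    cfg = compression if compression is not None else CompressionConfig()
    mags = compress_lgf(env.values, cfg)
    row_of = {e: i for i, e in enumerate(env.electrodes)}
    order = [e for e in cmap.cycle_order() if e in row_of]
    slot_s = cmap.slot_us * 1e-6
    times, channels, magnitudes = [], [], []
    for k in range(env.n_frames):
        t0 = k / cmap.rate
        slot = 0
        sel = selected_per_frame(k, mags[:, k])
        for e in order:
            if e not in sel:
                continue
            times.append(t0 + slot * slot_s)
            channels.append(e)
            magnitudes.append(mags[row_of[e], k])
            slot += 1
    seq = PulseSequence(
        times=np.array(times),
        channels=np.array(channels, dtype=np.int64),
        magnitudes=np.array(magnitudes),
        cu=np.full(len(times), -1, dtype=np.int64),
        cmap=cmap,
        duration=env.n_frames / cmap.rate,
    )
    seq.validate()
    return seq


def encode_cis(
    env: EnvelopeFrameSeries,
    cmap: ChannelMap,
    cfg: StrategyConfig | None = None,
    compression: CompressionConfig | None = None,
) -> PulseSequence:
    """Continuous interleaved sampling: every active channel pulses once
    per frame with its compressed band envelope as magnitude."""
    _check_feasible(cmap, cmap.n_channels)
    all_ch = set(env.electrodes)
    return _emit(env, cmap, lambda k, m: all_ch, compression)


def select_maxima(magnitudes, electrodes, n: int) -> tuple:
    """The ``n`` channels with the largest magnitude; ties go to the
    lower electrode number. Returns electrodes sorted ascending."""
    electrodes = tuple(int(e) for e in electrodes)
    if n > len(electrodes):
        raise ValueError(f"n={n} exceeds channel count {len(electrodes)}")
    keyed = sorted(zip(magnitudes, electrodes), key=lambda p: (-p[0], p[1]))
    return tuple(sorted(e for _, e in keyed[:n]))


def encode_ace(
    env: EnvelopeFrameSeries,
    cmap: ChannelMap,
    cfg: StrategyConfig | None = None,
    compression: CompressionConfig | None = None,
) -> PulseSequence:
    """N-of-M selection: in each frame only the n_maxima largest-envelope
    channels receive a pulse."""
    n = cfg.n_maxima if cfg is not None and cfg.n_maxima else cmap.n_maxima
    if n is None:
        raise ValueError("encode_ace requires n_maxima (in cfg or map)")
    if not 1 <= n <= env.n_channels:
        raise ValueError(f"n_maxima {n} outside 1..{env.n_channels}")
    _check_feasible(cmap, n)

    def pick(k, mags_k):
        return set(select_maxima(env.values[:, k], env.electrodes, n))

    return _emit(env, cmap, pick, compression)
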