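"""Pulse-sequence data model, clinical-current-unit mapping, electrodogram I/O.

The electrodogram — the time x electrode pattern of biphasic stimulation
pulses — is the central object of the package. Pulses carry a normalized
magnitude in [0, 1] (the post-compression channel amplitude) and optionally
a quantized clinical-current-unit (CU) level obtained from the electrode's
threshold (T) and comfortable (C) levels.

Conventions
-----------
* Time is seconds internally and integer microseconds on disk, so the
  round trip through the TSV format is exact.
* Electrode 22 is the most apical contact, electrode 1 the most basal.
  Within a stimulation cycle, channels fire apex-to-base (descending
  electrode number) unless the map overrides ``stim_order``.
* A magnitude-0 pulse is a non-stimulating timing slot: it keeps the cycle
  structure intact but is excluded from stimulating-pulse counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml


class ValidationError(ValueError):
    """A pulse sequence or channel map violates its invariants."""


class ParseError(ValueError):
    """An electrodogram file could not be parsed."""


def max_channels_per_cycle(
    rate: float, phase_us: float, ipg_us: float, overhead_us: float = 7.0
) -> int:
    """Number of interleaved channels that fit in one stimulation period.

    Each biphasic pulse occupies two phases plus the inter-phase gap, and
    the scheduler adds a fixed per-pulse overhead. At 900 pps with 62 us
    phases and an 8 us gap the period admits exactly 7 channels — the
    constraint that forces narrow clinical maps at long phase durations.
    """
    if rate <= 0 or phase_us <= 0 or ipg_us <= 0:
        raise ValueError("rate, phase_us and ipg_us must be positive")
    if overhead_us < 0:
        raise ValueError("overhead_us must be non-negative")
    period_us = 1e6 / rate
    slot_us = 2.0 * phase_us + ipg_us + overhead_us
    return int(math.floor(period_us / slot_us))


@dataclass(frozen=True)
class ChannelMap:
    """Stimulation map: active electrodes, timing and level parameters.

    ``t_levels`` / ``c_levels`` are clinical current units per electrode,
    aligned with ``electrodes``. ``mode`` (e.g. "MP1+2") is metadata only.
    """

    electrodes: tuple
    rate: float
    phase_us: float
    ipg_us: float
    t_levels: tuple
    c_levels: tuple
    mode: str = "MP1+2"
    n_maxima: int | None = None
    overhead_us: float = 7.0
    stim_order: tuple | None = None  # None -> apex-to-base (descending id)
    band_table: tuple | None = None  # per-channel (lo_hz, hi_hz), optional

    def __post_init__(self):
        electrodes = tuple(int(e) for e in self.electrodes)
        object.__setattr__(self, "electrodes", electrodes)
        object.__setattr__(self, "t_levels", tuple(float(t) for t in self.t_levels))
        object.__setattr__(self, "c_levels", tuple(float(c) for c in self.c_levels))
        if len(set(electrodes)) != len(electrodes):
            raise ValidationError("duplicate electrodes in map")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if self.phase_us <= 0:
            raise ValidationError("phase_us must be positive")
        if len(self.t_levels) != len(electrodes) or len(self.c_levels) != len(electrodes):
            raise ValidationError("t_levels/c_levels must align with electrodes")
        for e, t, c in zip(electrodes, self.t_levels, self.c_levels):
            if c < t:
                raise ValidationError(f"electrode {e}: c_level {c} < t_level {t}")
        if self.n_maxima is not None and not (1 <= self.n_maxima <= len(electrodes)):
            raise ValidationError(
                f"n_maxima {self.n_maxima} outside 1..{len(electrodes)}"
            )
        limit = max_channels_per_cycle(
            self.rate, self.phase_us, self.ipg_us, self.overhead_us
        )
        # feasibility applies to channels stimulated per cycle: n_maxima for
        # an N-of-M map, every electrode otherwise
        per_cycle = self.n_maxima if self.n_maxima is not None else len(electrodes)
        if per_cycle > limit:
            raise ValidationError(
                f"{per_cycle} channels per cycle exceed the {limit}-channel "
                f"limit at {self.rate} pps / {self.phase_us} us phase "
                f"(see max_channels_per_cycle)"
            )
        if self.stim_order is not None:
            if sorted(self.stim_order) != sorted(electrodes):
                raise ValidationError("stim_order must be a permutation of electrodes")
            object.__setattr__(self, "stim_order", tuple(int(e) for e in self.stim_order))

    @property
    def n_channels(self) -> int:
        return len(self.electrodes)

    @property
    def period_s(self) -> float:
        return 1.0 / self.rate

    @property
    def slot_us(self) -> float:
        return 2.0 * self.phase_us + self.ipg_us + self.overhead_us

    def cycle_order(self) -> tuple:
        """Within-cycle firing order (apex-to-base by default)."""
        if self.stim_order is not None:
            return self.stim_order
        return tuple(sorted(self.electrodes, reverse=True))

    def levels_for(self, electrode: int) -> tuple:
        i = self.electrodes.index(electrode)
        return self.t_levels[i], self.c_levels[i]


def map_from_yaml(path) -> ChannelMap:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    known = {
        "electrodes", "rate", "phase_us", "ipg_us", "t_levels", "c_levels",
        "mode", "n_maxima", "overhead_us", "stim_order", "band_table",
    }
    kwargs = {k: v for k, v in doc.items() if k in known}
    if "band_table" in kwargs and kwargs["band_table"] is not None:
        kwargs["band_table"] = tuple(tuple(b) for b in kwargs["band_table"])
    return ChannelMap(**kwargs)


def map_to_yaml(cmap: ChannelMap, path) -> None:
    doc = {
        "electrodes": list(cmap.electrodes),
        "rate": cmap.rate,
        "phase_us": cmap.phase_us,
        "ipg_us": cmap.ipg_us,
        "t_levels": list(cmap.t_levels),
        "c_levels": list(cmap.c_levels),
        "mode": cmap.mode,
        "n_maxima": cmap.n_maxima,
        "overhead_us": cmap.overhead_us,
    }
    if cmap.band_table is not None:
        doc["band_table"] = [list(b) for b in cmap.band_table]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class PulseSequence:
    """Time-ordered electrical pulse pattern referencing a channel map.

    Parallel arrays: ``times`` (s), ``channels`` (electrode ids),
    ``magnitudes`` ([0, 1]), ``cu`` (CU levels, -1 where unset).
    """

    times: np.ndarray
    channels: np.ndarray
    magnitudes: np.ndarray
    cu: np.ndarray
    cmap: ChannelMap
    duration: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_stimulating(self) -> int:
        return int(np.count_nonzero(self.magnitudes > 0))

    def stimulating_mask(self) -> np.ndarray:
        return self.magnitudes > 0

    def validate(self) -> None:
        """Check ordering, bounds, channel membership and interleaving."""
        t, ch, mag = self.times, self.channels, self.magnitudes
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValidationError("pulse times must be finite and >= 0")
        if np.any(np.diff(t) < 0):
            raise ValidationError("pulses not sorted by time")
        bad = np.flatnonzero((mag < 0) | (mag > 1))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"pulse {i} (t={t[i]:.6f}s, ch={ch[i]}) has magnitude "
                f"{mag[i]} outside [0, 1]"
            )
        members = set(self.cmap.electrodes)
        for i, c in enumerate(ch):
            if int(c) not in members:
                raise ValidationError(f"pulse {i} on channel {c} not in map")
        # interleaving: pulses on distinct channels may not overlap in time
        occupy_s = (2.0 * self.cmap.phase_us + self.cmap.ipg_us) * 1e-6
        if len(t) > 1:
            dt = np.diff(t)
            distinct = ch[1:] != ch[:-1]
            clash = np.flatnonzero(distinct & (dt < occupy_s - 1e-12))
            if clash.size:
                i = int(clash[0])
                raise ValidationError(
                    f"pulses {i} and {i + 1} overlap: gap {dt[i] * 1e6:.1f} us < "
                    f"pulse width {occupy_s * 1e6:.1f} us"
                )

    def subset(self, keep: np.ndarray) -> "PulseSequence":
        """Pruned copy retaining pulses where ``keep`` is True."""
        return PulseSequence(
            times=self.times[keep],
            channels=self.channels[keep],
            magnitudes=self.magnitudes[keep],
            cu=self.cu[keep],
            cmap=self.cmap,
            duration=self.duration,
        )


def make_sequence(pulses, cmap: ChannelMap) -> PulseSequence:
    """Build a validated PulseSequence from (time_s, channel, magnitude[, cu])
    records; pulses are sorted by time with ties broken by the map's
    within-cycle stimulation order."""
    n = len(pulses)
    times = np.empty(n)
    channels = np.empty(n, dtype=np.int64)
    mags = np.empty(n)
    cu = np.full(n, -1, dtype=np.int64)
    for i, rec in enumerate(pulses):
        times[i] = rec[0]
        channels[i] = rec[1]
        mags[i] = rec[2]
        if len(rec) > 3 and rec[3] is not None:
            cu[i] = rec[3]
    rank = {e: i for i, e in enumerate(cmap.cycle_order())}
    try:
        tie = np.array([rank[int(c)] for c in channels])
    except KeyError as exc:
        raise ValidationError(f"channel {exc.args[0]} not in map") from None
    order = np.lexsort((tie, times))
    times, channels, mags, cu = times[order], channels[order], mags[order], cu[order]
    duration = float(times[-1] + cmap.period_s) if n else 0.0
    seq = PulseSequence(
        times=times, channels=channels, magnitudes=mags, cu=cu,
        cmap=cmap, duration=duration,
    )
    seq.validate()
    return seq


def to_cu(magnitude: float, t_level: float, c_level: float) -> int:
    """Map a normalized magnitude onto the electrode's clinical dynamic
    range: 0 -> T level, 1 -> C level, linear in CU in between."""
    if c_level < t_level:
        raise ValidationError(f"c_level {c_level} < t_level {t_level}")
    if not 0.0 <= magnitude <= 1.0:
        raise ValidationError(f"magnitude {magnitude} outside [0, 1]")
    return int(round(t_level + magnitude * (c_level - t_level)))


def quantize_cu(seq: PulseSequence) -> PulseSequence:
    """Fill the CU column from each pulse's electrode T/C levels."""
    cu = np.empty(len(seq), dtype=np.int64)
    for i in range(len(seq)):
        t, c = seq.cmap.levels_for(int(seq.channels[i]))
        cu[i] = to_cu(float(seq.magnitudes[i]), t, c)
    return PulseSequence(
        times=seq.times.copy(), channels=seq.channels.copy(),
        magnitudes=seq.magnitudes.copy(), cu=cu, cmap=seq.cmap,
        duration=seq.duration,
    )


_HEADER = "time_us\tchannel\tmagnitude\tcu"


def write_electrodogram(seq: PulseSequence, path) -> None:
    """TSV electrodogram: integer microsecond times, 6-decimal magnitudes,
    map parameters on ``#`` metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# rate={seq.cmap.rate}\n")
        fh.write(f"# phase_us={seq.cmap.phase_us}\n")
        fh.write(f"# ipg_us={seq.cmap.ipg_us}\n")
        fh.write(f"# overhead_us={seq.cmap.overhead_us}\n")
        fh.write(f"# electrodes={','.join(str(e) for e in seq.cmap.electrodes)}\n")
        fh.write(f"# t_levels={','.join(repr(t) for t in seq.cmap.t_levels)}\n")
        fh.write(f"# c_levels={','.join(repr(c) for c in seq.cmap.c_levels)}\n")
        fh.write(f"# mode={seq.cmap.mode}\n")
        if seq.cmap.n_maxima is not None:
            fh.write(f"# n_maxima={seq.cmap.n_maxima}\n")
        fh.write(f"# duration_us={int(round(seq.duration * 1e6))}\n")
        fh.write(_HEADER + "\n")
        for i in range(len(seq)):
            cu = int(seq.cu[i])
            fh.write(
                f"{int(round(seq.times[i] * 1e6))}\t{int(seq.channels[i])}\t"
                f"{seq.magnitudes[i]:.6f}\t{cu if cu >= 0 else '-'}\n"
            )


def read_electrodogram(path) -> PulseSequence:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line == _HEADER:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                t_us = int(parts[0])
                ch = int(parts[1])
                mag = float(parts[2])
                cu = -1 if parts[3] == "-" else int(parts[3])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            rows.append((t_us * 1e-6, ch, mag, cu))
    try:
        cmap = ChannelMap(
            electrodes=[int(e) for e in meta["electrodes"].split(",")],
            rate=float(meta["rate"]),
            phase_us=float(meta["phase_us"]),
            ipg_us=float(meta["ipg_us"]),
            t_levels=[float(t) for t in meta["t_levels"].split(",")],
            c_levels=[float(c) for c in meta["c_levels"].split(",")],
            mode=meta.get("mode", "MP1+2"),
            n_maxima=int(meta["n_maxima"]) if "n_maxima" in meta else None,
            overhead_us=float(meta.get("overhead_us", 7.0)),
        )
    except KeyError as exc:
        raise ParseError(f"missing metadata line for {exc.args[0]}") from None
    seq = make_sequence(
        [(t, ch, m, cu if cu >= 0 else None) for t, ch, m, cu in rows], cmap
    )
    if "duration_us" in meta:
        seq.duration = int(meta["duration_us"]) * 1e-6
    return seq


def pulse_counts(seq: PulseSequence, stimulating_only: bool = False):
    """Per-channel and total pulse counts.

    With ``stimulating_only`` the magnitude-0 timing slots are excluded —
    the denominator used for removal fractions.
    """
    mask = seq.stimulating_mask() if stimulating_only else np.ones(len(seq), bool)
    per = {int(e): 0 for e in seq.cmap.electrodes}
    for c in seq.channels[mask]:
        per[int(c)] += 1
    return per, int(mask.sum())
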