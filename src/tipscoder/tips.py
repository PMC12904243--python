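"""Temporal-integrator pulse sparsification.

A sliding temporal-integrator (TI) window models forward and backward
masking around each stimulation pulse. For every pulse, the integrator
output of the channel's pulse train is compared with the output of the
same train with that pulse deleted; the pulse is kept only when deleting
it changes the integrator output by more than a decision criterion (in
dB), i.e. only when the pulse is predicted to be detectable rather than
masked by its same-channel neighbours.

The window is asymmetric: maskers *earlier* than the window centre decay
with a slow double exponential (forward masking, time constants tau_b1
and tau_b2 mixed by weight r), maskers *later* than the centre with a
fast single exponential (backward masking, tau_a). The integrator output
on the channel's time grid is

    O(t) = sum_i  a_i^q * W(t_i - t)

with q = 2 in the intensity domain (default) or q = 1 in the magnitude
domain. The decision statistic is the maximum, over grid times within the
window support of the target pulse, of the level difference between the
with-pulse and without-pulse outputs; grid points where the without-pulse
output falls below a small floor are excluded, and a pulse whose support
contains only such points (an isolated pulse) receives a +inf statistic
and is never removed.

Because the statistic is a level *ratio*, rescaling a channel's
magnitudes leaves every decision unchanged; the criterion is therefore
calibrated to a target removal fraction rather than fixed in absolute
terms (``calibrate_criterion``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pulsecore import PulseSequence


@dataclass(frozen=True)
class TIWindow:
    """Temporal-integrator masking window W(t).

    W(t) = (1-r)*exp(t/tau_b1) + r*exp(t/tau_b2)   for t < 0
    W(t) = exp(-t/tau_a)                           for t >= 0
    and 0 outside +/- half_support. W(0) = 1 from both sides.

    ``dt`` is the sampling step of the channel grid; None means one
    stimulation period of the sequence being processed.
    """

    tau_b1: float = 4.6e-3
    tau_b2: float = 16.6e-3
    tau_a: float = 3.5e-3
    r: float = 0.17
    half_support: float = 75e-3
    dt: float | None = None

    def __post_init__(self):
        if min(self.tau_b1, self.tau_b2, self.tau_a) <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if self.half_support <= 0:
            raise ValueError("half_support must be positive")


def window_value(t, w: TIWindow):
    """Evaluate W(t); accepts scalars or arrays."""
    t = np.asarray(t, dtype=np.float64)
    out = np.where(
        t < 0,
        (1.0 - w.r) * np.exp(t / w.tau_b1) + w.r * np.exp(t / w.tau_b2),
        np.exp(-t / w.tau_a),
    )
    out = np.where(np.abs(t) > w.half_support, 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DecisionConfig:
    """Pulse-keep rule configuration.

    ``criterion_db``: pulses whose decision statistic falls below this are
    removed. ``log_base`` chooses 10*log10 (intensity-style levels,
    default) or 20*log10. ``domain`` chooses whether pulse magnitudes
    enter the integrator squared ("intensity", default) or linearly
    ("magnitude"). ``floor_eps`` floors the without-pulse output before
    the log. ``scan_mode`` "batch" evaluates every pulse against the
    original pattern; "sequential" scans in time order against the
    already-pruned pattern.
    """

    criterion_db: float = 1.3
    log_base: str = "10log10"  # "10log10" | "20log10"
    domain: str = "intensity"  # "intensity" | "magnitude"
    floor_eps: float = 1e-12
    scan_mode: str = "batch"  # "batch" | "sequential"

    def __post_init__(self):
        if self.log_base not in ("10log10", "20log10"):
            raise ValueError(f"unknown log_base {self.log_base!r}")
        if self.domain not in ("intensity", "magnitude"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.floor_eps <= 0:
            raise ValueError("floor_eps must be positive")
        if self.scan_mode not in ("batch", "sequential"):
            raise ValueError(f"unknown scan_mode {self.scan_mode!r}")

    @property
    def log_factor(self) -> float:
        return 10.0 if self.log_base == "10log10" else 20.0

    @property
    def exponent(self) -> float:
        return 2.0 if self.domain == "intensity" else 1.0


@dataclass
class RemovalReport:
    """Outcome of one pruning pass."""

    criterion_db: float
    per_channel: dict  # electrode -> {"kept": int, "removed": int}
    n_stimulating: int
    n_removed: int
    log_base: str
    domain: str
    scan_mode: str
    stat_min_db: float = float("nan")
    stat_median_db: float = float("nan")
    n_isolated: int = 0

    @property
    def removal_fraction(self) -> float:
        return self.n_removed / self.n_stimulating if self.n_stimulating else 0.0

    def to_dict(self) -> dict:
        return {
            "criterion_db": self.criterion_db,
            "per_channel": {
                str(e): dict(v) for e, v in sorted(self.per_channel.items())
            },
            "n_stimulating": self.n_stimulating,
            "n_removed": self.n_removed,
            "removal_fraction": self.removal_fraction,
            "log_base": self.log_base,
            "domain": self.domain,
            "scan_mode": self.scan_mode,
            "stat_min_db": self.stat_min_db,
            "stat_median_db": self.stat_median_db,
            "n_isolated": self.n_isolated,
        }


def _sampled_window(w: TIWindow, dt: float):
    """(w_arr, h): w_arr[j] = W((h - j) * dt) for j = 0..2h.

    Indexed so that a pulse at grid index i contributes
    a^q * w_arr[(m - i) + h] to the integrator output at grid index m.
    """
    h = int(round(w.half_support / dt))
    j = np.arange(2 * h + 1)
    return window_value((h - j) * dt, w), h


def integrator_output(train, w: TIWindow, domain: str = "intensity", dt=None):
    """Temporal-integrator output of a single-channel train on its grid.

    ``train`` holds pulse magnitudes at grid steps of ``dt`` (defaults to
    ``w.dt``). Output[m] = sum_n train[n]^q * W((n - m)*dt): a single unit
    pulse reproduces the window shape around the pulse, and superposition
    holds exactly in the chosen domain.
    """
    dt = dt if dt is not None else w.dt
    if dt is None:
        raise ValueError("dt must be given (argument or w.dt)")
    x = np.asarray(train, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("train must be non-negative")
    q = 2.0 if domain == "intensity" else 1.0
    w_arr, h = _sampled_window(w, dt)
    full = np.convolve(x**q, w_arr)
    return full[h:h + len(x)]


def _channel_grid(seq: PulseSequence, idx: np.ndarray, dt: float, h: int):
    """Snap the pulses at ``idx`` onto a grid of step dt; returns
    (grid_index array, grid length, max snap error seconds).

    The grid extends one full window support beyond the last pulse: the
    decision statistic can peak in the forward-masking tail after a
    pulse, so truncating at the pulse would bias decisions near the end.
    """
    t = seq.times[idx]
    gi = np.round(t / dt).astype(np.int64)
    err = float(np.max(np.abs(t - gi * dt))) if len(t) else 0.0
    n = int((gi.max() if len(gi) else 0) + h + 1)
    return gi, n, err


def _stats_for_channel(seq, idx, w, cfg, dt):
    """Decision statistics for the (stimulating) pulses at ``idx``, all
    evaluated against the full original pattern (batch semantics)."""
    q = cfg.exponent
    lf = cfg.log_factor
    eps = cfg.floor_eps
    w_arr, h = _sampled_window(w, dt)
    gi, n, err = _channel_grid(seq, idx, dt, h)
    if err > dt * 0.5 + 1e-12:
        warnings.warn(
            f"pulse snapped to grid with error {err * 1e3:.3f} ms > dt/2",
            stacklevel=2,
        )
    x = np.zeros(n)
    np.add.at(x, gi, seq.magnitudes[idx] ** q)
    O = np.convolve(x, w_arr)[h:h + n]
    stats = np.empty(len(idx))
    for k in range(len(idx)):
        i = int(gi[k])
        a_q = float(seq.magnitudes[idx[k]]) ** q
        lo, hi = max(0, i - h), min(n - 1, i + h)
        seg = O[lo:hi + 1]
        contrib = a_q * w_arr[(lo - i + h):(hi - i + h) + 1]
        without = seg - contrib
        valid = without > eps
        if not np.any(valid):
            stats[k] = np.inf
            continue
        vals = lf * (np.log10(seg[valid]) - np.log10(without[valid]))
        stats[k] = float(vals.max())
    return stats


def _all_stats(seq: PulseSequence, w: TIWindow, cfg: DecisionConfig):
    """Batch decision statistics for every stimulating pulse.

    Returns (stat array aligned with seq pulses; NaN for magnitude-0
    timing slots, which are never removal candidates).
    """
    dt = w.dt if w.dt is not None else seq.cmap.period_s
    stats = np.full(len(seq), np.nan)
    stim = seq.stimulating_mask()
    for e in seq.cmap.electrodes:
        idx = np.flatnonzero((seq.channels == e) & stim)
        if len(idx):
            stats[idx] = _stats_for_channel(seq, idx, w, cfg, dt)
    return stats


def decision_statistic(
    seq: PulseSequence, pulse_index: int, w: TIWindow, cfg: DecisionConfig
) -> float:
    """Decision statistic (dB) of one pulse against the full pattern."""
    if not 0 <= pulse_index < len(seq):
        raise IndexError(f"pulse index {pulse_index} out of range")
    if seq.magnitudes[pulse_index] <= 0:
        raise ValueError("magnitude-0 slot has no decision statistic")
    dt = w.dt if w.dt is not None else seq.cmap.period_s
    e = int(seq.channels[pulse_index])
    idx = np.flatnonzero((seq.channels == e) & seq.stimulating_mask())
    stats = _stats_for_channel(seq, idx, w, cfg, dt)
    return float(stats[np.flatnonzero(idx == pulse_index)[0]])


def _sequential_keep(seq, w, cfg, criterion):
    """Time-ordered scan removing pulses from the evolving pattern."""
    dt = w.dt if w.dt is not None else seq.cmap.period_s
    q, lf, eps = cfg.exponent, cfg.log_factor, cfg.floor_eps
    w_arr, h = _sampled_window(w, dt)
    keep = np.ones(len(seq), dtype=bool)
    stim = seq.stimulating_mask()
    for e in seq.cmap.electrodes:
        idx = np.flatnonzero((seq.channels == e) & stim)
        if not len(idx):
            continue
        gi, n, _ = _channel_grid(seq, idx, dt, h)
        x = np.zeros(n)
        np.add.at(x, gi, seq.magnitudes[idx] ** q)
        O = np.convolve(x, w_arr)[h:h + n]
        for k in range(len(idx)):  # idx is time-ordered within channel
            i = int(gi[k])
            a_q = float(seq.magnitudes[idx[k]]) ** q
            lo, hi = max(0, i - h), min(n - 1, i + h)
            contrib = a_q * w_arr[(lo - i + h):(hi - i + h) + 1]
            seg = O[lo:hi + 1]
            without = seg - contrib
            valid = without > eps
            if not np.any(valid):
                stat = np.inf
            else:
                stat = float(
                    (lf * (np.log10(seg[valid]) - np.log10(without[valid]))).max()
                )
            if stat < criterion:
                keep[idx[k]] = False
                O[lo:hi + 1] = without  # pulse leaves the pattern
    return keep


def apply_tips(
    seq: PulseSequence, w: TIWindow, cfg: DecisionConfig
) -> tuple:
    """Prune masked pulses; returns (pruned sequence, RemovalReport).

    Pruning only ever deletes pulses — kept pulses retain their original
    times, channels and magnitudes. Magnitude-0 timing slots pass through
    untouched and are excluded from all counts.
    """
    stim = seq.stimulating_mask()
    if cfg.scan_mode == "batch":
        stats = _all_stats(seq, w, cfg)
        keep = ~stim | (stats >= cfg.criterion_db)
        finite = stats[stim & np.isfinite(stats)]
        n_isolated = int(np.count_nonzero(np.isinf(stats[stim])))
    else:
        keep = _sequential_keep(seq, w, cfg, cfg.criterion_db)
        finite = np.array([])
        n_isolated = 0
    per_channel = {}
    for e in seq.cmap.electrodes:
        on_e = (seq.channels == e) & stim
        kept = int(np.count_nonzero(on_e & keep))
        per_channel[int(e)] = {
            "kept": kept,
            "removed": int(np.count_nonzero(on_e)) - kept,
        }
    n_stim = int(stim.sum())
    report = RemovalReport(
        criterion_db=cfg.criterion_db,
        per_channel=per_channel,
        n_stimulating=n_stim,
        n_removed=n_stim - int(np.count_nonzero(keep & stim)),
        log_base=cfg.log_base,
        domain=cfg.domain,
        scan_mode=cfg.scan_mode,
        stat_min_db=float(finite.min()) if len(finite) else float("nan"),
        stat_median_db=float(np.median(finite)) if len(finite) else float("nan"),
        n_isolated=n_isolated,
    )
    return seq.subset(keep), report


def calibrate_criterion(
    seq: PulseSequence,
    target_fraction: float,
    w: TIWindow,
    cfg: DecisionConfig,
) -> float:
    """Criterion (dB) that removes ``target_fraction`` of stimulating pulses.

    Batch mode inverts the statistic distribution exactly (empirical
    quantile); sequential mode bisects on the criterion until the achieved
    fraction is within 0.005 of the target or 40 iterations elapse.
    """
    if not 0.0 <= target_fraction < 1.0:
        raise ValueError("target_fraction must be in [0, 1)")
    n_stim = seq.n_stimulating
    if n_stim == 0:
        raise ValueError("sequence has no stimulating pulses")
    if n_stim < 100:
        warnings.warn(
            f"only {n_stim} stimulating pulses; calibration is coarse",
            stacklevel=2,
        )
    stats = _all_stats(seq, w, cfg)
    stats = stats[~np.isnan(stats)]
    finite = stats[np.isfinite(stats)]
    frac_finite = len(finite) / len(stats)
    if target_fraction > 0 and target_fraction >= frac_finite:
        raise ValueError(
            "target unreachable: isolated pulses cannot be removed "
            f"(finite-statistic fraction {frac_finite:.3f})"
        )
    srt = np.sort(stats)
    k = int(round(target_fraction * len(stats)))
    if k == 0:
        return float(srt[0] - 1.0)
    batch_criterion = float(srt[k]) if k < len(stats) else float(finite.max() + 1.0)
    if cfg.scan_mode == "batch":
        return batch_criterion

    def achieved(c):
        keep = _sequential_keep(
            seq, w, DecisionConfig(
                criterion_db=c, log_base=cfg.log_base, domain=cfg.domain,
                floor_eps=cfg.floor_eps, scan_mode="sequential",
            ), c,
        )
        stim = seq.stimulating_mask()
        return 1.0 - np.count_nonzero(keep & stim) / n_stim

    lo, hi = float(srt[0] - 1.0), float(finite.max() + 1.0)
    c = batch_criterion
    for _ in range(40):
        f = achieved(c)
        if abs(f - target_fraction) <= 0.005:
            break
        if f < target_fraction:
            lo = c
        else:
            hi = c
        c = 0.5 * (lo + hi)
    return float(c)
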