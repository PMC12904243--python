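import numpy as np
import pytest

from tipscoder import ChannelMap, DecisionConfig, TIWindow
from tipscoder.tips import window_value


@pytest.fixture
def cis_map():
    """8-channel CIS map: every other electrode across the array."""
    return ChannelMap(
        electrodes=[6, 8, 10, 12, 14, 16, 18, 20],
        rate=900, phase_us=25.0, ipg_us=8.0,
        t_levels=[100.0] * 8, c_levels=[200.0] * 8,
    )


@pytest.fixture
def ace_map():
    """Full 22-electrode map with 8-of-22 selection."""
    return ChannelMap(
        electrodes=list(range(1, 23)),
        rate=900, phase_us=25.0, ipg_us=8.0,
        t_levels=[100.0] * 22, c_levels=[200.0] * 22,
        n_maxima=8,
    )


@pytest.fixture
def single_channel_map():
    return ChannelMap(
        electrodes=[10], rate=900, phase_us=25.0, ipg_us=8.0,
        t_levels=[100.0], c_levels=[200.0],
    )


def brute_force_decisions(seq, w: TIWindow, cfg: DecisionConfig):
    """Independent decision oracle: explicit per-pulse, per-grid-point sums.

    Recomputes every decision statistic from the window closed form alone
    (no convolution, no shared code path with tips.apply_tips): for each
    stimulating pulse, O(t) = sum_i a_i^q W(t_i - t) is evaluated term by
    term on the channel grid with and without the pulse, the level
    difference is maximized over non-floored grid points, and the pulse
    is kept iff the statistic reaches the criterion (isolated -> +inf).
    Returns (keep boolean array, stat array with NaN on magnitude-0 slots).
    """
    dt = w.dt if w.dt is not None else seq.cmap.period_s
    q = 2.0 if cfg.domain == "intensity" else 1.0
    lf = 10.0 if cfg.log_base == "10log10" else 20.0
    n = len(seq)
    keep = np.ones(n, dtype=bool)
    stats = np.full(n, np.nan)
    for k in range(n):
        if seq.magnitudes[k] <= 0:
            continue
        ch = seq.channels[k]
        others = [
            (round(seq.times[j] / dt), float(seq.magnitudes[j]) ** q)
            for j in range(n)
            if j != k and seq.channels[j] == ch and seq.magnitudes[j] > 0
        ]
        gi = round(seq.times[k] / dt)
        a_q = float(seq.magnitudes[k]) ** q
        h = int(round(w.half_support / dt))
        best = -np.inf
        any_valid = False
        for m in range(max(0, gi - h), gi + h + 1):
            o_without = sum(
                aj * window_value((gj - m) * dt, w) for gj, aj in others
            )
            if o_without <= cfg.floor_eps:
                continue
            any_valid = True
            o_with = o_without + a_q * window_value((gi - m) * dt, w)
            best = max(best, lf * (np.log10(o_with) - np.log10(o_without)))
        stats[k] = best if any_valid else np.inf
        keep[k] = stats[k] >= cfg.criterion_db
    return keep, stats
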