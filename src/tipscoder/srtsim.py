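"""Adaptive speech-reception-threshold (SRT) simulation with model listeners.

The SRT is the SNR at which a listener reports 50% of words correctly.
The protocol simulated here presents matrix-style sentences (5 scored
words each) in noise, starting at 0 dB SNR, adapts the SNR toward the
50%-correct point, bounds it to [-15, +30] dB, and estimates the SRT as
the mean presented SNR at the last 8 staircase reversals. Two tracks are
averaged; if they disagree by more than 4 dB or either track produced
too few reversals, a third track is run and all three are averaged.

A human listener is replaced by a psychometric-function model: each word
is reported correctly with probability
(1 - lapse) * logistic(4 * slope * (snr - srt50)), so at snr = srt50
(and no lapses) exactly half the words are correct. The SNR update rule
is word-score proportional — dSNR = -step * (prop_correct - 0.5) / 0.5 —
with the step halving after each of the first 4 reversals (5 dB down to
a 1 dB floor). The cited clinical procedure's exact internals are not
public in this form; this rule reproduces its target (50% correct) and
its reversal-based estimator, and all constants are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ListenerModel:
    """Psychometric stand-in for a human listener."""

    srt50: float  # dB SNR at 50% words correct
    slope: float = 0.15  # proportion/dB at threshold
    lapse: float = 0.0
    words_per_trial: int = 5

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        if self.words_per_trial < 1:
            raise ValueError("words_per_trial must be >= 1")


@dataclass(frozen=True)
class TrackConfig:
    start_snr: float = 0.0
    snr_bounds: tuple = (-15.0, 30.0)
    trials_per_track: int = 20  # two 10-sentence lists
    reversals_for_srt: int = 8
    retest_delta: float = 4.0
    initial_step: float = 5.0
    min_step: float = 1.0
    step_halvings: int = 4

    def __post_init__(self):
        lo, hi = self.snr_bounds
        if lo >= hi:
            raise ValueError("snr_bounds must be ordered")
        if self.reversals_for_srt < 2:
            raise ValueError("reversals_for_srt must be >= 2")


def listener_prob(listener: ListenerModel, snr: float) -> float:
    """Per-word probability correct at the given SNR."""
    z = 4.0 * listener.slope * (snr - listener.srt50)
    return (1.0 - listener.lapse) * float(expit(z))


@dataclass
class TrackResult:
    snrs: np.ndarray  # presented SNR per trial
    scores: np.ndarray  # proportion words correct per trial
    reversal_trials: np.ndarray  # trial indices where direction reversed
    srt: float
    complete: bool  # enough reversals for the estimate


def run_track(
    listener: ListenerModel, cfg: TrackConfig, seed: int
) -> TrackResult:
    """One adaptive staircase; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.snr_bounds
    snr = float(np.clip(cfg.start_snr, lo, hi))
    step = cfg.initial_step
    snrs, scores, reversals = [], [], []
    prev_sign = 0
    n_reversals = 0
    for trial in range(cfg.trials_per_track):
        snrs.append(snr)
        p = listener_prob(listener, snr)
        n_correct = rng.binomial(listener.words_per_trial, p)
        prop = n_correct / listener.words_per_trial
        scores.append(prop)
        update = -step * (prop - 0.5) / 0.5
        sign = int(np.sign(update))
        if sign != 0:
            if prev_sign != 0 and sign != prev_sign:
                reversals.append(trial)
                n_reversals += 1
                if n_reversals <= cfg.step_halvings:
                    step = max(step / 2.0, cfg.min_step)
            prev_sign = sign
        snr = float(np.clip(snr + update, lo, hi))
    snrs = np.array(snrs)
    reversals = np.array(reversals, dtype=int)
    complete = len(reversals) >= cfg.reversals_for_srt
    if len(reversals):
        tail = reversals[-cfg.reversals_for_srt:]
        srt = float(snrs[tail].mean())
    else:
        srt = float(snrs[-1])
    return TrackResult(
        snrs=snrs, scores=np.array(scores),
        reversal_trials=reversals, srt=srt, complete=complete,
    )


@dataclass
class SrtMeasurement:
    srt: float
    tracks: list
    retested: bool


def measure_srt(
    listener: ListenerModel, cfg: TrackConfig | None = None, seed: int = 0
) -> SrtMeasurement:
    """Final SRT per protocol: two tracks, third on disagreement.

    A third track is run when the first two differ by more than
    ``retest_delta`` dB or either produced too few reversals; the final
    SRT is then the mean of all three, otherwise the mean of two.
    """
    cfg = cfg or TrackConfig()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    t1 = run_track(listener, cfg, int(seeds[0]))
    t2 = run_track(listener, cfg, int(seeds[1]))
    need_retest = (abs(t1.srt - t2.srt) > cfg.retest_delta
                   or not t1.complete or not t2.complete)
    if need_retest:
        t3 = run_track(listener, cfg, int(seeds[2]))
        return SrtMeasurement(
            srt=float(np.mean([t1.srt, t2.srt, t3.srt])),
            tracks=[t1, t2, t3], retested=True,
        )
    return SrtMeasurement(
        srt=float(np.mean([t1.srt, t2.srt])), tracks=[t1, t2], retested=False,
    )
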