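# Methods

## Overview

`tipscoder` models a pulse-sparsification post-processor for cochlear-implant
(CI) sound coding. A standard envelope-extraction strategy (CIS or ACE)
converts audio into an electrodogram — a time × electrode pattern of biphasic
current pulses. The sparsifier then removes pulses that a temporal-masking
model predicts are inaudible: each pulse is kept only if deleting it changes
the output of a sliding temporal integrator by more than a criterion number
of decibels. Removing pulses saves stimulation power; restoring comfortable
loudness afterwards requires raising the global current level, which costs
part of it back. A linear power model quantifies the net saving.

## Encoding chain

**Calibration.** Input audio is normalized to a per-signal RMS of −20 dB FS.

**Pre-emphasis.** A first-order Chebyshev Type II high-pass (stopband edge
4 kHz, stopband attenuation 3 dB, at the 16 kHz analysis rate) tilts the
spectrum up by ~3 dB toward high frequency before analysis. Because the
stopband ripple of a first-order Chebyshev II design is only 3 dB, this is a
gentle shelving filter, not a brick wall. The stopband edge is configurable;
it must lie strictly below Nyquist, so an "8 kHz edge" variant is not
realizable at the 16 kHz analysis rate and is not shipped as a preset. No
automatic gain control or noise reduction is applied anywhere in the chain.

**Filterbank.** Audio is resampled (polyphase) to 16 kHz and analyzed with a
128-point periodic-Hann FFT, one frame per stimulation period (the hop is
the fractional sample count `fs/rate`, with frame starts rounded to the
nearest sample). The 22 analysis bands occupy FFT bins 2–63 (187.5–7937.5 Hz)
with the conventional allocation of 1–8 bins per band, wider toward high
frequency. Maps with fewer channels group the 22 bands into contiguous runs
spanning the full range (e.g. eight channels take runs of 2,2,3,3,3,3,3,3
bands, low to high). Low bands map to apical electrodes.

The band envelope is the root-power sum of the bins in the band, scaled so a
bin-centred unit-amplitude tone yields an envelope of 1. A coherent vector
sum of the complex bins was considered and rejected: with a Hann window the
±1-bin leakage is in antiphase with the centre bin (DFT weights −0.25, 0.5,
−0.25), so a tone centred inside a band would cancel almost completely.

**Compression.** The loudness-growth function maps envelopes onto [0, 1]:
`v = log(1 + ρ(p − b)/(s − b)) / log(1 + ρ)` with base `b = 0`, saturation
`s = 0.39` and steepness `ρ = 416.2`, clipped at both ends. ρ is the
conventional emulator default; the chain's behaviour downstream is invariant
to it up to the calibration step, because the pruning criterion is
re-calibrated per pattern (see below).

**CIS.** Every active channel fires once per stimulation cycle with its
compressed envelope as magnitude. Channels fire apex-to-base within the
cycle (configurable; no published convention mandates an order), each pulse
occupying a scheduling slot of `2·phase + inter-phase gap + overhead` µs.
The per-pulse overhead defaults to 7 µs, chosen so that the number of
channels that fit in one period, `floor(period / slot)`, gives 7 channels at
900 pps with 62 µs phases and ≥ 8 channels at 50 µs — both clinically
observed configurations.

**ACE (N-of-M).** In each cycle only the `n_maxima` channels with the largest
band envelope fire; ties go to the lower electrode number. With N = M the
pulse set is identical to CIS. Map feasibility is checked against channels
stimulated per cycle (N), not the electrode count.

**Zero-magnitude slots.** Frames whose compressed envelope is 0 still emit
timing slots flagged non-stimulating, so the cycle structure survives; all
removal fractions and pulse counts refer to stimulating pulses only.

## The masking model

The temporal-integrator window is asymmetric around its centre:

    W(t) = (1−r)·exp(t/τ_b1) + r·exp(t/τ_b2)   t < 0   (forward masking)
    W(t) = exp(−t/τ_a)                          t ≥ 0   (backward masking)

with defaults τ_b1 = 4.6 ms, τ_b2 = 16.6 ms, τ_a = 3.5 ms, r = 0.17, and
support truncated at ±75 ms (beyond which the slowest tail has decayed by
more than 39 dB). The integrator output of a channel's pulse train on its
time grid (one step per stimulation period) is

    O(t) = Σᵢ aᵢ^q · W(tᵢ − t)

so a masker *earlier* than the evaluation point contributes through the
slowly decaying forward branch, as forward masking requires. q = 2 by
default (intensity domain; q = 1 selectable).

**Decision device.** For each stimulating pulse, the statistic is

    D = max over grid times t within ±75 ms of the pulse of
        L(O_with(t)) − L(O_without(t))

where O_without is the integrator output of the same train with the target
pulse deleted and L = 10·log₁₀ (20·log₁₀ selectable). Grid points where
O_without falls below a floor (10⁻¹²) are excluded from the maximum: at the
edge of the support the target pulse can be the only contributor, and a
floored denominator there would report an arbitrarily large level change
that reflects the floor, not masking. A pulse whose whole support is floored
has no same-channel context at all — it is isolated, receives a +∞
statistic, and is never removed. The pulse is kept iff D ≥ criterion.

Because D is a level *ratio*, rescaling all magnitudes on a channel leaves
every decision unchanged. The absolute dB criterion is therefore meaningful
only relative to a specific pattern's statistic distribution, which is why
the package calibrates the criterion to a target removal fraction instead of
trusting any fixed dB value across materials.

**Scan modes.** In batch mode (default) every statistic is evaluated against
the original pattern, making decisions order-independent and
permutation-invariant. In sequential mode pulses are scanned in time order
against the already-pruned pattern; removed pulses stop masking later ones,
so sequential pruning is never more aggressive than batch at the same
criterion.

**Calibration.** Batch mode inverts the empirical statistic distribution
exactly: the criterion for a target removal fraction f is the f-quantile of
the per-pulse statistics, achieving f to within one pulse. Sequential mode
bisects on the criterion until the achieved fraction is within 0.005 of the
target (≤ 40 iterations). Calibration refuses targets exceeding the fraction
of non-isolated pulses and warns below 100 stimulating pulses.

**Numerical details.** Pulses are snapped to the channel grid by rounding
(worst-case error half a period; a warning is raised if exceeded — ACE slot
offsets within a cycle make sub-period offsets routine). The evaluation grid
extends one full window support beyond the last pulse, because the statistic
of a late pulse can peak in its forward-masking tail. Within machine
precision the convolution path is identical to the explicit double-sum
oracle used in the tests.

## Power model

The radio-frequency coil link is taken to consume a fixed `coil_fraction`
(default 0.9) of total device power, scaling linearly with stimulation
level; the remaining 10% (implant electronics) is constant. With a fraction
`f` of pulses retained and a fractional charge increase `δ` of the global
comfortable level,

    saving(%) = 100 · coil_fraction · (1 − f·(1 + δ)).

Charge steps are expressed in clinical current units (CU). The device
current ladder is exactly logarithmic with 40/255 dB per CU
(`CU_STEP_DB_EXACT`), conventionally printed as 0.157 dB; the bundled charge
table's nonzero entries are all whole numbers of exact CU steps to within
0.02 percentage points, whereas the rounded 0.157 step drifts by up to 0.06
at 14+ steps.

`table2_report` reproduces a published loudness-balancing table
cell-for-cell. Its per-participant rows use the exact kept fractions (1/2,
2/3); its average row follows the published convention of applying the model
to the rounded column-average charge with the kept fraction rounded to two
decimals (2/3 → 0.67). The two conventions differ only in the
one-third-removed condition, where the published table is internally
inconsistent between its cells and its average; the bundled expected values
mirror the table as printed.

## Synthetic stimuli

The generators exist so the full chain is testable without recordings; all
are pure functions of (spec, seed).

- **Speech-shaped noise**: Gaussian noise shaped in the frequency domain to
  third-octave *band levels* (equal levels ⇒ equal band energies). The
  default spectrum is a generic long-term-average speech shape peaking near
  400 Hz with high-frequency roll-off — a stand-in, not a measurement of any
  specific speech corpus. Bands truncated by Nyquist retain their full
  target level in the remaining bandwidth.
- **Speech-like tokens**: source-filter syllables — harmonic voicing
  (F0 100–250 Hz) under formant-like resonances near 500/1500/2500 Hz,
  unvoiced high-passed bursts, raised-cosine syllabic envelopes at 3–5 Hz
  with silent gaps. They mimic speech's modulation spectrum and level
  statistics, not its phonetics; nothing here is intelligible.
- **Babble**: a sum of `n_talkers` independent tokens (default 20),
  unit-RMS. More talkers ⇒ shallower envelope modulation and more Gaussian
  amplitude statistics, the qualitative signatures that matter for masking.
- **SNR mixing** varies the noise level only: the speech samples pass
  through bit-identical, and the noise segment is drawn at random from a
  longer noise signal.

Passing tests on these materials demonstrate the machinery (calibration,
conservation, monotonicity), not performance on real speech: the tokens lack
phonetic structure, co-articulation and f0 prosody, and the babble lacks the
spectral idiosyncrasies of any recorded crowd.

## SRT simulation

The adaptive speech-reception-threshold protocol is simulated with model
listeners so the measurement procedure can be exercised end to end. A
listener is a psychometric function: per-word probability
`(1 − lapse)·logistic(4·slope·(snr − srt50))`, 5 scored words per trial.
Tracks start at 0 dB SNR, are bounded to [−15, +30] dB, run 20 trials (two
10-sentence lists), and estimate the SRT as the mean presented SNR at the
last 8 reversals. Two tracks are averaged; a third is run (and all three
averaged) if they disagree by more than 4 dB or either under-reversed.

The SNR update is word-score proportional, `ΔSNR = −step·(prop − 0.5)/0.5`,
with the step halving after each of the first 4 reversals (5 dB initial,
1 dB floor); a reversal is a sign change between consecutive nonzero
updates. The clinical procedure this emulates targets 50% correct with a
reversal-based estimate but does not publish its update constants in this
form; the rule here is a documented stand-in with every constant
configurable. With the defaults, 200 seeded measurements on a listener with
srt50 = 2 dB and slope 0.15/dB recover the threshold with |mean bias| well
under 1 dB (computed in the test suite). No intelligibility model links
processed stimuli to listener parameters: human outcome statistics are out
of scope.

## Problem sizes in the tests

The acceptance-level checks run the CIS chain on 10 s of seeded
speech-shaped noise (72 000 stimulating pulses across 8 channels at
900 pps), calibrate to 50% removal, and verify the achieved fraction within
±1%. Small-sequence oracles (≤ 10 pulses) are checked exhaustively against
an explicit double-sum implementation of the decision device. SRT recovery
uses 200 seeded measurements. These sizes were chosen as the smallest that
exercise every code path with stable statistics.

## Known limitations

- Masking is modelled per channel; across-electrode spread of excitation
  and across-channel masking are not modelled.
- The decision device is non-causal (±75 ms look-around); no real-time
  variant is provided.
- Absolute charge (nC) is not computed unless the caller supplies baseline
  current and phase duration; the power model works in relative charge.
- The electrical stimulation mode (e.g. MP1+2) is metadata only.
- Synthetic stimuli are stand-ins; no claim of spectral equivalence to any
  recorded test material is made.
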