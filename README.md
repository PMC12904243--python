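# tipscoder

Pulse-pattern sparsification for cochlear-implant (CI) sound coding.

CI speech processors stimulate the auditory nerve with trains of biphasic
current pulses. Many of those pulses are perceptually redundant: a pulse
arriving a few milliseconds after a stronger one on the same electrode falls
inside the temporal-masking window and is unlikely to be heard. `tipscoder`
implements the full chain needed to study this idea on the desk:

- **Encoding** — an envelope-extraction front end (RMS calibration,
  Chebyshev-II pre-emphasis, 128-point FFT filterbank, loudness-growth
  compression) feeding CIS and ACE (N-of-M) pulse-pattern encoders with
  interleaved cycle timing and clinical-current-unit (CU) quantization.
- **Sparsification** — a sliding temporal-integrator masking window
  `W(t)` (double-exponential forward branch, τ_b1 = 4.6 ms, τ_b2 = 16.6 ms,
  r = 0.17; single-exponential backward branch, τ_a = 3.5 ms) drives a
  per-pulse decision device: a pulse is kept iff deleting it changes the
  integrator output by at least a criterion (dB). The criterion is
  calibrated to a target removal fraction (e.g. 50%).
- **Power model** — net savings from removing pulses and then restoring
  loudness: `saving = 90% · (1 − f_kept·(1 + δq))`, with charge steps on
  the exact CU ladder (40/255 dB per CU).
- **Evaluation tooling** — deterministic synthetic stimuli (speech-shaped
  noise, 20-talker babble proxy, speech-like tokens, SNR mixing) and a
  simulation of the adaptive speech-reception-threshold (SRT) protocol
  with psychometric model listeners.

It is aimed at hearing-prosthesis researchers who want a transparent,
fully tested reference implementation of masking-based pulse pruning and
its power arithmetic, without any proprietary coder or recorded corpus.

## Worked example

Generate 5 s of speech-shaped noise, encode it with an 8-channel CIS map at
900 pps, calibrate the pruning criterion to remove half the pulses, prune,
and estimate the power saving if loudness restoration then costs a 5.57%
charge increase:

```sh
tipscoder synth --kind ssn --duration 5 --seed 1 --out ssn.wav
tipscoder encode --map examples/map8.yaml --strategy cis --in ssn.wav --out pattern.tsv
tipscoder calibrate --in pattern.tsv --target 0.5
tipscoder tips --in pattern.tsv --criterion-db 0.5039 --out pruned.tsv --report report.json
tipscoder power --fraction-removed 0.5 --charge-increase-pct 5.57
tipscoder srt-sim --srt50 2.0 --slope 0.15 --seed 7
```

prints

```
wrote ssn.wav (5.00s at 16000 Hz)
wrote pattern.tsv: 36000 slots, 36000 stimulating pulses
0.5039
removed 17994/36000 pulses (50.0%)
42.49
SRT = 1.62 dB SNR (retested: False)
```

Reading the numbers: the encoder emits 8 channels × 900 pps × 5 s = 36 000
pulses; the calibrated criterion (0.5039 dB on this pattern) removes half of
them to within the quantile's granularity; halving the pulse count while paying a 5.57% charge increase
nets a 42.49% power saving under the 90%-coil linear model; and one
simulated adaptive measurement on a listener with a true threshold of
2.0 dB SNR returns 1.62 dB without triggering the retest rule. (The
criterion's absolute dB value is material-specific — the decision statistic
is a level ratio, so only the calibrated removal fraction transfers across
stimuli.)

The same operations are available as a library:

```python
from tipscoder import (ChannelMap, DecisionConfig, NoiseSpec, TIWindow,
                       analyze_envelopes, apply_tips, calibrate_criterion,
                       encode_cis, gen_ssn, net_power_saving, normalize_rms)

cmap = ChannelMap(electrodes=[6, 8, 10, 12, 14, 16, 18, 20], rate=900,
                  phase_us=25, ipg_us=8,
                  t_levels=[100] * 8, c_levels=[200] * 8)
audio = normalize_rms(gen_ssn(NoiseSpec(seed=1), 5.0), -20.0)
seq = encode_cis(analyze_envelopes(audio, cmap), cmap)
crit = calibrate_criterion(seq, 0.5, TIWindow(), DecisionConfig())
pruned, report = apply_tips(seq, TIWindow(), DecisionConfig(criterion_db=crit))
print(report.removal_fraction, net_power_saving(0.5, 0.0557))  # 0.5 42.49
```

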