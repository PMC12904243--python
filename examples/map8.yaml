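electrodes: [6, 8, 10, 12, 14, 16, 18, 20]
rate: 900
phase_us: 25.0
ipg_us: 8.0
t_levels: [100, 100, 100, 100, 100, 100, 100, 100]
c_levels: [200, 200, 200, 200, 200, 200, 200, 200]
mode: MP1+2
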