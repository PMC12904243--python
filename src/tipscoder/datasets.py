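"""Bundled example data: measured loudness-balancing charge increases.

Per-participant percentage increases in the global comfortable-level
charge needed to restore equal loudness after pulse sparsification,
for three conditions: half the pulses removed from a CIS pattern, one
third removed from an ACE pattern, and half removed from an ACE pattern.
These are the inputs to the net power-savings model; participants absent
from a condition are marked None.
"""

# condition -> per-participant charge increase (%); None = not tested
CHARGE_PERCENT = {
    "tips50_cis": [0.00, 0.00, 1.82, 11.44, 15.54, 0.00, 13.48, 5.57,
                   3.68, 1.82, 3.68, 15.54],
    "tips33_ace": [5.57, 5.57, 28.77, 11.44, 5.57, 15.54, 5.57, 7.49,
                   33.50, 13.48, -3.55, 28.77],
    "tips50_ace": [11.44, 7.49, 43.50, 19.79, 21.98, 51.49, 9.45, 11.44,
                   46.12, 26.46, 7.49, 48.78],
}
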