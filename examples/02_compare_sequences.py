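"""Image quality across GE/SE EPI and FR/PR SPEN under the air field.

Reconstructs one image per sequence from the same distorted phantom and
tabulates SNR, centroid displacement along the low-bandwidth axis,
support Dice against ground truth, and the peak percent BOLD change of a
short matched run.
"""

from spenfmri import io as sio

cfg = sio.merge_config(sio.default_config(), {"seed": 1})
table = sio.run_compare_sequences(cfg)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("-> the SPEN variants keep the object support (Dice ~1) where EPI "
      "warps it; the partially refocused variant trades a little of that "
      "robustness (Delta = 4 ms of T2* weighting) for a larger BOLD "
      "response than full refocusing.")
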