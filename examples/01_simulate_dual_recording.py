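"""Simulate one dual-device day and inspect the planted ground truth.

The generator produces a 100 Hz hip stream, a 32 Hz chest stream and a 1 Hz
heart-rate channel, with true non-wear episodes planted on the hip device:
short ones clustered in the morning, long ones at night.
"""

import nonwear as nw

config = nw.evaluation_config(seed=1)
hip, chest, heart_rate, truth = nw.simulate_dual_recording(config)

print(f"hip:   {hip.n_samples} samples at {hip.rate:g} Hz "
      f"({hip.duration_s / 3600:.0f} h from {hip.start_time})")
print(f"chest: {chest.n_samples} samples at {chest.rate:g} Hz")
print(f"heart rate: {len(heart_rate)} per-second values, "
      f"mean {heart_rate[heart_rate > 0].mean():.0f} bpm while worn")
print()
print("planted non-wear episodes (half-open minute intervals):")
print(truth.episodes.to_string(index=False))
nonwear_min = int(truth.minute_labels.values.sum())
print(f"\n{nonwear_min} of {len(truth.minute_labels)} minutes are true non-wear "
      f"({100 * nonwear_min / len(truth.minute_labels):.1f}%)")
# Each episode row says when the hip device was off and whether the chest
# device (and with it the heart-rate channel) was off too.
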