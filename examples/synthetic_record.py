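"""One synthetic channel through the full feature pipeline.

Generates a 10-minute record whose envelope phases are coupled only inside
a labeled seizure window, then shows that the windowed PLV separates the
seizure from the background.
"""

import numpy as np

from envsync import SynthConfig, generate_record, process_channel

cfg = SynthConfig(
    record_id="demo", duration_s=600.0, n_channels=1,
    seizures=[(300.0, 390.0)], coupling_in=0.9, coupling_out=0.0,
    noise_sd=0.1, seed=7,
)
record, annotations = generate_record(cfg)
plv = process_channel(record.samples[0], record.fs, channel="EEG00")

inside = (plv.window_start_s >= 300) & (plv.window_start_s + plv.window_len_s <= 390)
outside = (plv.window_start_s + plv.window_len_s <= 290) | (plv.window_start_s >= 400)
peak = float(plv.window_start_s[int(np.argmax(plv.values))])

print(f"seizure window: {annotations[0].start_s:.0f}-{annotations[0].end_s:.0f} s")
print(f"mean PLV inside seizure : {plv.values[inside].mean():.3f}")
print(f"mean PLV outside        : {plv.values[outside].mean():.3f}")
print(f"max-PLV window starts at: {peak:.0f} s")
print()
print("Envelope phase locking rises sharply inside the coupled window, so the")
print("channel's maximum-PLV position lands inside the annotated seizure.")
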