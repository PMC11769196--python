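"""Simulate a labeled activity session and log it in the frame-CSV dialect.

Builds a short session (sitting, walking, a fall, laying), writes the
8x8 frames and per-frame labels to CSV, reads them back, and summarizes
the per-frame temperature sums per state.  The sums are the scalar
statistic everything downstream works on: static postures give tightly
concentrated sums, the fall transient sticks out by tens of units.
"""

import numpy as np

import thermofall as tf

script = tf.ActivityScript(
    (
        tf.Segment("sitting", 320),
        tf.Segment("move_fb", 320),
        tf.Segment("fall", 160),
        tf.Segment("laying", 320),
    ),
    seed=42,
)
series, labels = tf.simulate_session(script, tf.SceneConfig())

tf.write_frames_csv(series, "session_frames.csv")
tf.write_labels_csv(labels, "session_labels.csv")
back = tf.read_frames_csv("session_frames.csv")
print(f"wrote and re-read {len(back)} frames ({len(labels)} labels)")

sums = tf.sum_series(back)
labels_arr = np.asarray(labels)
print(f"{'state':8s} {'n':>4s} {'mean sum':>9s} {'sd':>6s} {'max dev':>8s}")
for state in dict.fromkeys(labels):
    v = sums.values[labels_arr == state]
    print(f"{state:8s} {len(v):4d} {v.mean():9.1f} {v.std():6.2f} "
          f"{np.abs(v - np.median(v)).max():8.1f}")
print("\nStatic states sit near 64*25 + area*8 with sub-1% spread; the fall")
print("segment's transient frames deviate by an order of magnitude more.")
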