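"""End-to-end fall detection: calibrate a threshold, scan a stream.

Calibrates tau from normal-activity windows (1.25x their worst min-EMD),
then slides a 160-frame window over a stream containing one scripted
fall and reports the debounced fall events.  The fall windows' minimum
EMD jumps well above anything routine activity produces.
"""

import thermofall as tf

scene = tf.SceneConfig()

# calibration: non-overlapping windows of labeled routine activity
profiles = []
for k, state in enumerate(("sitting", "standing", "laying", "move_fb", "move_ud")):
    sums = tf.sum_series(tf.simulate_state(state, 160 * 5, scene, seed=300 + k))
    profiles += [tf.emd_profile(w, state_label=state)
                 for w in tf.sliding_windows(sums, 160, 160)]
tau = tf.calibrate_threshold(profiles, quantile=1.0)
print(f"calibrated tau = {tau:.3f} from {len(profiles)} normal windows")

# a stream: standing, one fall, then laying still
script = tf.ActivityScript(
    (tf.Segment("standing", 320), tf.Segment("fall", 160), tf.Segment("laying", 320)),
    seed=99,
)
series, _ = tf.simulate_session(script, scene)
cfg = tf.ClassifierConfig(tau=tau, window_len=160, step=32)
decisions = tf.classify_stream(tf.sum_series(series), cfg)

print(f"{'window':>6s} {'start':>6s} {'label':7s} {'best fit':10s} {'min EMD':>8s}")
for d in decisions:
    print(f"{d.window_index:6d} {d.start_frame:6d} {d.label:7s} "
          f"{d.best_fit.family:10s} {d.best_fit.emd:8.3f}")

for e in tf.fall_events(decisions, cfg):
    print(f"\nfall event: frames {e.start_frame}-{e.end_frame} "
          f"({e.n_windows} windows, peak EMD {e.peak_emd:.3f})")
print("windows overlapping the scripted fall (frames 320-480) are flagged;")
print("quiet standing/laying windows stay far below tau.")
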