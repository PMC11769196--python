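"""Fit the ten candidate families to one window and score each by EMD.

A 160-frame sitting window is reduced to its sums, every family is
fitted with its designated estimator, and the Earth Mover's Distance
between the empirical distribution and each fitted CDF is printed.
Low EMD = the family matches the window; the concentrated, symmetric
sitting sums are matched by Normal/Beta-like families, while the
support-pinned Exponential and Pareto fits are off by orders of
magnitude — exactly the contrast the fall detector exploits.
"""

import thermofall as tf

sums = tf.sum_series(tf.simulate_state("sitting", 160, tf.SceneConfig(), seed=7))
profile = tf.emd_profile(sums, state_label="sitting", estimator="integral")

print(f"{'family':12s} {'EMD':>10s}  fitted parameters")
for res in profile.results:
    params = ", ".join(f"{k}={v}" for k, v in tf.fit_to_record(res.fit).items()
                       if k not in ("family", "method"))
    print(f"{res.family:12s} {res.emd:10.3f}  {params}")

bf = tf.best_fit(profile)
print(f"\nbest fit: {bf.family} at EMD {bf.emd:.3f} (temperature-sum units)")
print("EMD is the area between the empirical step CDF and the fitted CDF,")
print("so it is comparable across families and across windows.")
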