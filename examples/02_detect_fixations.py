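"""Round-trip a fixation sequence through gaze rendering and detection.

Samples fixations from a gaze archetype, renders them as a 100-Hz gaze
trace (stationary dwells joined by 300 deg/s saccades), and runs the
velocity-threshold fixation detector on the result. The detector should
recover the fixation count and centroids almost exactly on noise-free data.
"""

import numpy as np

import gazehmm as gz

rng = np.random.default_rng(7)
spec = gz.make_archetype("distributed", seed=1)
truth = gz.sample_fixation_sequence(spec, n_fixations=10, rng=rng)

samples = gz.render_gaze_samples(truth, rate_hz=100, saccade_velocity_degps=300)
detected = gz.detect_fixations(samples)

print(f"rendered {len(samples)} gaze samples from {len(truth)} fixations")
print(f"detected {len(detected)} fixations")
err = np.linalg.norm(detected.xy - truth.xy, axis=1)
print(f"max centroid error: {err.max():.4f} deg (velocity threshold "
      f"100 deg/s, minimum duration 60 ms)")
# A max error well below 0.1 deg shows the detector's centroids agree with
# the generating fixation positions.
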