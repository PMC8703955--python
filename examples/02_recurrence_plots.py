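"""From raw gyroscope samples to 29 x 29 recurrence-plot frames.

Walks through the encoding one step at a time: a 5-sample window per axis
is concatenated into a 15-vector, midpoint interpolation brings it to 29
entries, and pairwise absolute differences give the distance-only
recurrence plot.  With 30 input frames and a 20-frame horizon, one minute
of walking yields 1747 supervised forecasting samples.
"""

import numpy as np

import rpfno as rp

profile = rp.make_subject_profile("s1", "walking", seed=7)
stream = rp.generate_motion_stream(profile, duration_s=60, rate_hz=30)

cfg = rp.EncodingConfig()  # Tw=5, stride 1, T=30, horizon 20
vectors, ends = rp.window_axes(stream, cfg)
print(f"{vectors.shape[0]} windows of length {vectors.shape[1]} (3 axes x {cfg.window_size})")

interp = rp.interpolate_window(vectors[0])
print(f"after midpoint interpolation: {interp.shape[0]} entries")

frame = rp.recurrence_plot(interp)
print(f"recurrence plot: {frame.shape[0]} x {frame.shape[1]}, "
      f"symmetric={np.allclose(frame, frame.T)}, zero diagonal={np.allclose(np.diag(frame), 0)}")

dataset = rp.encode_stream(stream, cfg)
print(f"dataset: {dataset.n_samples} samples, inputs {dataset.inputs.shape[1:]}, "
      f"targets {dataset.targets.shape[1:]}")

# sensor fusion: pair the gyro with an accelerometer via cross recurrence
accel = rp.companion_accelerometer_stream(profile, duration_s=60, rate_hz=30)
fused = rp.encode_stream(stream, cfg, accel_stream=accel)
crp = fused.inputs[0, 0]
print(f"cross recurrence plot: {crp.shape[0]} x {crp.shape[1]}, "
      f"symmetric={np.allclose(crp, crp.T)} (CRPs are generally asymmetric)")
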