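"""Train a small Fourier neural operator and forecast 0.6 s ahead.

Trains at a desk-scale profile (reduced width/epochs so the script runs in
about a minute on a laptop CPU), reports test MSE in normalized frame
units, and demonstrates mesh invariance: the same trained weights evaluate
on coarser 23 x 23 and 17 x 17 grids without retraining, while the
convolutional baseline is locked to its training resolution.
"""

import rpfno as rp
from rpfno.nets import FNOConfig, CNNConfig

profile = rp.make_subject_profile("s1", "walking", seed=7)
stream = rp.generate_motion_stream(profile, duration_s=35, rate_hz=30)
dataset = rp.encode_stream(stream)

cfg = rp.TrainingConfig(epochs=12, seed=11)
model, curves, test = rp.train_forecaster(dataset, "fno", cfg, FNOConfig(width=16))
print(f"FNO: {model.param_count} parameters, train MSE {curves.train[-1]:.4f} "
      f"-> test MSE {rp.evaluate_mse(model, test):.4f} (normalized units)")

# mesh invariance: rebuild frames with a shorter window (coarser grid)
for tw in (4, 3):
    small = rp.encode_stream(stream, rp.EncodingConfig(window_size=tw))
    pred = model.evaluate_at_resolution(small.inputs[:4] / model.scale)
    print(f"window {tw} -> grid {small.grid_size} x {small.grid_size}: "
          f"prediction stack {pred.shape[1:]}, same {model.param_count} weights")

# the CNN baseline cannot change resolution: its head is tied to 29 x 29
cnn, _, _ = rp.train_forecaster(
    dataset, "cnn", rp.TrainingConfig(epochs=1, seed=11),
    CNNConfig(channels=6, hidden=(96, 96)),
)
small = rp.encode_stream(stream, rp.EncodingConfig(window_size=4))
try:
    cnn.forward(small.inputs[:2] / cnn.scale)
except ValueError as err:
    print(f"CNN at 23 x 23: rejected ({err})")
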