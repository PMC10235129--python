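"""Training-time augmentation and test-time preprocessing of one frame.

The training stack rescales to [0, 1] then applies a random shear (0.2),
zoom (0.2) and a 50% horizontal flip; the test-time pipeline rescales,
resizes to the model's 150x150 input and mean-filters.
"""

import numpy as np

import echophase as ep

frame = ep.generate_frame("ED", ep.SyntheticConfig(seed=0))
print(f"raw frame: shape={frame.image.shape}, range=[{frame.image.min()}, "
      f"{frame.image.max()}]")

rng = np.random.default_rng(0)
cfg = ep.AugmentConfig()  # shear 0.2, zoom 0.2, flip enabled, rescale 1/255
for k in range(3):
    aug = ep.augment(frame.image, cfg, rng)
    print(f"augmented variant {k}: shape={aug.shape}, "
          f"range=[{aug.min():.3f}, {aug.max():.3f}]")
# every variant keeps the input shape and lands in [0, 1]

test_ready = ep.test_time_pipeline(frame.image, height=150, width=150,
                                   denoise_kernel=3)
print(f"test-time output: shape={test_ready.shape}, "
      f"mean={test_ready.mean():.4f}")
# 112x112 raw frames are resized to the 150x150x1 tensor the model expects
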