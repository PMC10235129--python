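"""The regularised-MSE loss and the 9-layer classifier, by hand.

The training objective is L = MSE + beta * mean(residual): the signed mean
term shifts the loss by beta times the average under-prediction, which
sharpens the penalty on wrongly scored frames.
"""

import numpy as np

import echophase as ep

y_true = np.array([1.0, 1.0, 0.0, 0.0])
y_pred = np.array([0.9, 0.4, 0.2, 0.1])
print(f"MSE              = {ep.mse(y_true, y_pred):.4f}")
print(f"mean residual    = {ep.mean_error(y_true, y_pred):.4f}")
print(f"custom (b=0.1)   = {ep.custom_loss(y_true, y_pred, beta=0.1):.4f}")
print(f"MAE baseline     = {ep.baseline_loss(y_true, y_pred, kind='mae'):.4f}")
print(f"cross-entropy    = "
      f"{ep.baseline_loss(y_true, y_pred, kind='cross_entropy'):.4f}")

model = ep.build_model(ep.ModelConfig(), seed=0)
print(f"\nnamed layers ({len(model.layer_names)}): "
      f"{', '.join(model.layer_names)}")
print("feature-map trace:",
      " -> ".join(f"{h}x{w}" for h, w in model.cfg.spatial_trace()))
print(f"trainable parameters: {model.n_parameters():,}")
print(f"mean |weight| at initialisation: {ep.average_abs_weight(model):.5f}")
# each 2x2 max-pool keeps 1 of 4 activations (75% discarded)
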