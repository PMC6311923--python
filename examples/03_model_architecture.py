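"""The network: gated-inception stages, pyramid pooling, one parameter set
for every fragment length.

Shows the exact reference parameter count, the 7-bins-per-channel pyramid
output, and that forwards at different lengths share one output shape.
"""

import numpy as np

from dhsnet import build_model, count_parameters, predict
from dhsnet.nn import SpatialPyramidPool

model = build_model()
print(f"trainable parameters: {count_parameters(model):,}")

spp = SpatialPyramidPool((1, 2, 4))
x = np.array([[[1.0, 2.0, 3.0, 4.0]]])  # 1 sample, 1 channel, length 4
print("SPP of (1,2,3,4):", spp.forward(x)[0])
print("-> level 1 mean, level 2 halves, level 4 quarters: 7 bins/channel")

rng = np.random.default_rng(0)
for length in (200, 317, 555, 800):
    batch = [(rng.random((length, 4)) < 0.25).astype("float32")]
    probs = predict(model, batch)
    print(f"length {length}: class probabilities {np.round(probs[0], 3)}")
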