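"""Build the network and inspect its shapes, receptive field and size.

Prints the stage-by-stage output shapes for a 512-sample window, the
analytic receptive field of the dilated pyramid, and the trainable
parameter count (~569 k for the default five-class configuration).
"""

import numpy as np

from rdpnet import (ModelConfig, build_model, count_parameters,
                    receptive_field)
from rdpnet.model import dcpm_layer_specs

cfg = ModelConfig()
model = build_model(cfg, seed=0).eval()

x = np.zeros((1, 1, 512), dtype=np.float32)
logits = model.forward(x)
print("input          (1, 1, 512)")
print("RCM output    ", model._stage["rcm"].shape)    # (1, 128, 128)
print("DCPM output   ", model._stage["dcpm"].shape)   # (1, 128, 128)
print("fused features", model._stage["fused"].shape)  # (1, 512)
print("logits        ", logits.shape)                 # (1, 5)

rf = receptive_field(dcpm_layer_specs(cfg))
print(f"pyramid receptive field: {rf} samples "
      f"({rf / 173.61 * 1000:.0f} ms at the Bonn sampling rate)")

total = count_parameters(model)
print(f"trainable parameters: {total:,} (~{round(total / 1000)} k)")
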