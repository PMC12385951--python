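"""Compare the five entropy descriptors on simple feature maps.

Differential entropy (the default fusion descriptor) grows with the
log-variance of a channel; the histogram and spectral variants respond
to the shape of the value or power distribution instead.
"""

import numpy as np

from rdpnet import EntropySpec, entropy_descriptor

rng = np.random.default_rng(0)
quiet = rng.normal(0, 0.5, size=(1, 1024))    # low-variance channel
active = rng.normal(0, 2.0, size=(1, 1024))   # high-variance channel
fm = np.vstack([quiet, active])

for kind in ("differential", "shannon", "renyi", "spectral", "tsallis"):
    h = entropy_descriptor(fm, EntropySpec(kind=kind))
    print(f"{kind:>12}: quiet {h[0]:7.4f}  active {h[1]:7.4f} nats")

# Differential entropy separates the two by ln(2/0.5) ~ 1.39 nats; the
# histogram descriptors barely move because both channels are Gaussian
# in shape, just differently scaled.
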