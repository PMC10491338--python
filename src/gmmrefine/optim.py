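"""Adam optimizer on normalized parameter blocks.

All gradient-based searches in this package (GMM fitting, per-particle pose
refinement, conformation-to-pose conversion) use Adam with the learning
rates the protocol prescribes.  Because Adam's effective step size equals
the learning rate in the units of the parameters, parameters are expressed
in *normalized* coordinates before optimization: Euler angles in fractions
of a full turn (1 unit = 360 deg), translations and Gaussian centers in
fractions of the box size, amplitudes and widths relative to their initial
scale.  This makes a learning rate of 1e-3 mean "up to ~0.36 deg / ~0.1% of
the box per step" regardless of box size.
"""

from __future__ import annotations

import numpy as np


class Adam:
    """Per-parameter adaptive moment estimation; state matches the shapes
    of the parameter arrays passed to :meth:`step`."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        """Update each array in ``params`` in place from ``grads`` (same keys)."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for key, g in grads.items():
            p = params[key]
            if key not in self._m:
                self._m[key] = np.zeros_like(p)
                self._v[key] = np.zeros_like(p)
            m = self._m[key]
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
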