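"""Sequential container for layers."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Network:
    """A plain sequential network.

    Parameters
    ----------
    layers : list of Layer
    """

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, *, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def layer_outputs(self, x, *, train=False, rng=None):
        """Forward pass returning the output of every layer (for shape audits)."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
            outs.append(x)
        return outs

    def state(self):
        """Copy of all parameter values (for determinism checks / checkpoints)."""
        return [np.array(p.value, copy=True) for p in self.params()]

    def load_state(self, state):
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state length does not match parameter count")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = v
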