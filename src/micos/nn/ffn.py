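"""Feed-forward network (ReLU hidden layers) with manual backprop."""

from __future__ import annotations

import numpy as np


class FFN:
    """A fully connected network with ReLU activations between layers and a
    linear output, used as the endpoint species-to-metabolite head and for
    the discretized-gLV metabolite predictor.
    """

    def __init__(self, layer_dims: list[int], seed: int = 0):
        if len(layer_dims) < 2:
            raise ValueError("need at least input and output dims")
        self.layer_dims = list(layer_dims)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for li, (din, dout) in enumerate(zip(layer_dims[:-1], layer_dims[1:])):
            k = 1.0 / np.sqrt(din)
            self.params[f"W{li}"] = rng.uniform(-k, k, size=(dout, din))
            self.params[f"b{li}"] = np.zeros(dout)
        self.n_layers = len(layer_dims) - 1

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X: (batch, d_in) -> (batch, d_out), plus caches for backward."""
        a = X
        caches = []
        for li in range(self.n_layers):
            W, b = self.params[f"W{li}"], self.params[f"b{li}"]
            z = a @ W.T + b
            caches.append((a, z))
            a = np.maximum(z, 0.0) if li < self.n_layers - 1 else z
        return a, caches

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, caches: list, dY: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Returns (parameter grads, grad wrt input X)."""
        grads: dict[str, np.ndarray] = {}
        da = dY
        for li in reversed(range(self.n_layers)):
            a_prev, z = caches[li]
            dz = da if li == self.n_layers - 1 else da * (z > 0)
            grads[f"W{li}"] = dz.T @ a_prev
            grads[f"b{li}"] = dz.sum(axis=0)
            da = dz @ self.params[f"W{li}"]
        return grads, da
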