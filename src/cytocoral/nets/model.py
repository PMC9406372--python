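"""Sequential model container and parameter counting."""

from __future__ import annotations

import copy
from typing import Iterable

import numpy as np

from .layers import Dropout, Layer


class Sequential:
    """A plain ordered stack of layers sharing one forward/backward pass."""

    def __init__(self, layers: Iterable[Layer]):
        self.layers: list[Layer] = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate ``dout`` through cached activations; returns dx."""
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainable(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            if not layer.frozen:
                out.extend(zip(layer.params, layer.grads))
        return out

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class scores in evaluation mode, batched to bound memory."""
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1

    def seed_dropout(self, seed: int) -> None:
        """Reseed every dropout layer deterministically from ``seed``."""
        ss = np.random.SeedSequence(seed)
        drops = [l for l in self.layers if isinstance(l, Dropout)]
        for layer, child in zip(drops, ss.spawn(max(1, len(drops)))):
            layer.rng = np.random.Generator(np.random.PCG64(child))

    def clone(self) -> "Sequential":
        return copy.deepcopy(self)


def count_trainable_params(model: Sequential) -> int:
    """Total size of all parameters in non-frozen layers."""
    return sum(layer.param_count() for layer in model.layers)
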