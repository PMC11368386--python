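"""Minimal feed-forward network core used by the autoencoder, denoiser and classifier.

All models in this package are small multilayer perceptrons, and the
classifier-guidance machinery needs gradients of the network output with
respect to its *input* (not only its parameters), so layers implement
explicit forward/backward passes over NumPy arrays. Everything is float64
and deterministic given the seed used at initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "SiLU",
    "Softplus",
    "MLP",
    "Adam",
    "sinusoidal_embedding",
    "softmax",
]


class Linear:
    """Affine layer ``y = x W + b`` with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0


class SiLU:
    """x * sigmoid(x); smooth, non-saturating activation."""

    def __init__(self):
        self._x = None
        self._s = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        self._x = x
        self._s = expit(x)
        return x * self._s

    def backward(self, g: np.ndarray) -> np.ndarray:
        s = self._s
        return g * (s * (1.0 + self._x * (1.0 - s)))

    def params(self):
        return []

    def zero_grad(self) -> None:
        pass


class Softplus:
    """log(1 + exp(x)), used as a non-negative output map for the decoder."""

    def __init__(self):
        self._s = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        self._s = expit(x)
        return np.logaddexp(0.0, x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._s

    def params(self):
        return []

    def zero_grad(self) -> None:
        pass


class LeakyReLU:
    """max(x, alpha*x). Used as the decoder output map: near-ReLU behavior
    without dead output units (the small negative slope keeps gradients
    informative); exact non-negativity is applied by the decode step."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.alpha * g)

    def params(self):
        return []

    def zero_grad(self) -> None:
        pass


class MLP:
    """A stack of Linear layers with SiLU between them.

    ``widths`` is the full sequence of layer sizes, input first, output last.
    ``out_activation`` may be None, "softplus" (non-negative output) or
    "silu".
    """

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 out_activation: str | None = None):
        if len(widths) < 2:
            raise ValueError("MLP needs at least an input and an output width")
        self.widths = list(widths)
        self.layers: list = []
        for i in range(len(widths) - 1):
            self.layers.append(Linear(widths[i], widths[i + 1], rng))
            if i < len(widths) - 2:
                self.layers.append(SiLU())
        if out_activation == "softplus":
            self.layers.append(Softplus())
        elif out_activation == "leaky_relu":
            self.layers.append(LeakyReLU())
        elif out_activation == "silu":
            self.layers.append(SiLU())
        elif out_activation is not None:
            raise ValueError(f"unknown out_activation {out_activation!r}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Propagate an upstream gradient; returns the gradient w.r.t. the input."""
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- serialization -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError("parameter count mismatch when loading state")
        for (p, _), a in zip(own, arrays):
            if p.shape != a.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {a.shape}")
            p[...] = a


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def sinusoidal_embedding(steps: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Transformer-style sinusoidal embedding of integer timesteps.

    Parameters
    ----------
    steps : array of shape (n,) of step indices.
    dim : embedding dimension (must be even).
    """
    if dim % 2 != 0:
        raise ValueError("embedding dim must be even")
    steps = np.asarray(steps, dtype=float).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = steps * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
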