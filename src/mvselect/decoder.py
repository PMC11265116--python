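"""Per-view decoder networks mapping the shared latent code to view space.

A decoder is a small multilayer perceptron ``Z -> sigma(Z W_1 + b_1) -> ...``
whose final layer is affine by default: standardized data are signed and
unbounded, so a bounded output activation could not reconstruct them (an
output activation remains available for fidelity experiments).  Gradients are
computed by hand-written reverse-mode accumulation; the networks are tiny, so
no autodiff framework is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# activation -> (f, f') evaluated elementwise; derivative takes the *input*
_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "leaky_relu": (
        lambda x: np.where(x > 0, x, 0.01 * x),
        lambda x: np.where(x > 0, 1.0, 0.01),
    ),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "sigmoid": (
        lambda x: 1.0 / (1.0 + np.exp(-x)),
        lambda x: (s := 1.0 / (1.0 + np.exp(-x))) * (1.0 - s),
    ),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class DecoderSpec:
    """Architecture of one view's decoder.

    Parameters
    ----------
    latent_dim : int
        K, width of the shared code.
    output_dim : int
        View width p (stage 1) or number of selected features p' (stage 2).
    depth : int
        Number of affine layers (>= 1); depth 1 is a single affine map.
    hidden_width : int
        Width c_d of every hidden layer.
    activation : str
        One of relu, leaky_relu, tanh, sigmoid, linear; applied after every
        layer except the last.
    output_activation : str
        Activation after the final layer; "linear" (affine output) by default.
    """

    latent_dim: int
    output_dim: int
    depth: int = 3
    hidden_width: int = 256
    activation: str = "relu"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.depth < 1 or self.hidden_width < 1:
            raise ValueError("latent_dim, depth and hidden_width must be >= 1")
        for name in (self.activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(
                    f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
                )

    def layer_dims(self) -> list[tuple[int, int]]:
        """(fan_in, fan_out) of each affine layer, chaining K -> c -> ... -> p."""
        dims = []
        fan_in = self.latent_dim
        for layer in range(self.depth):
            fan_out = self.output_dim if layer == self.depth - 1 else self.hidden_width
            dims.append((fan_in, fan_out))
            fan_in = fan_out
        return dims


@dataclass
class DecoderParams:
    """Weights and biases of one decoder; biases broadcast across samples."""

    spec: DecoderSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "DecoderParams":
        return DecoderParams(
            self.spec,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )

    def flat(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def check_shapes(self) -> None:
        for layer, ((fi, fo), W, b) in enumerate(
            zip(self.spec.layer_dims(), self.weights, self.biases)
        ):
            if W.shape != (fi, fo):
                raise ValueError(
                    f"layer {layer}: weight shape {W.shape}, expected {(fi, fo)}"
                )
            if b.shape != (fo,):
                raise ValueError(
                    f"layer {layer}: bias shape {b.shape}, expected {(fo,)}"
                )


def init_params(spec: DecoderSpec, rng: np.random.Generator | int) -> DecoderParams:
    """He-style fan-in initialization: W ~ N(0, 2/fan_in), biases zero."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    weights, biases = [], []
    for fan_in, fan_out in spec.layer_dims():
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return DecoderParams(spec, weights, biases)


def forward(params: DecoderParams, Z: np.ndarray) -> np.ndarray:
    """Decode the latent code: returns the n x p reconstruction."""
    return forward_cached(params, Z)[0]


def forward_cached(
    params: DecoderParams, Z: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass returning the output and per-layer pre-activations.

    The cache holds [h_0 (=Z), a_1, h_1, a_2, h_2, ..., a_L] where a_l is the
    affine pre-activation of layer l and h_l its post-activation output.
    """
    Z = np.asarray(Z, dtype=float)
    spec = params.spec
    if Z.ndim != 2 or Z.shape[1] != spec.latent_dim:
        raise ValueError(
            f"latent code shape {Z.shape} incompatible with latent_dim={spec.latent_dim}"
        )
    cache = [Z]
    h = Z
    L = spec.depth
    for layer, (W, b) in enumerate(zip(params.weights, params.biases)):
        if h.shape[1] != W.shape[0]:
            raise ValueError(
                f"layer {layer}: input width {h.shape[1]} != weight fan-in {W.shape[0]}"
            )
        a = h @ W + b
        cache.append(a)
        name = spec.output_activation if layer == L - 1 else spec.activation
        h = _ACTIVATIONS[name][0](a)
        if layer < L - 1:
            cache.append(h)
    return h, cache


def backward(
    params: DecoderParams,
    cache: list[np.ndarray],
    grad_out: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Backpropagate d(loss)/d(output) through the decoder.

    Returns (weight grads, bias grads, d(loss)/dZ).
    """
    spec = params.spec
    L = spec.depth
    gW = [None] * L
    gb = [None] * L
    delta = grad_out
    for layer in range(L - 1, -1, -1):
        a = cache[2 * layer + 1]
        h_in = cache[2 * layer]
        name = spec.output_activation if layer == L - 1 else spec.activation
        delta = delta * _ACTIVATIONS[name][1](a)
        gW[layer] = h_in.T @ delta
        gb[layer] = delta.sum(axis=0)
        delta = delta @ params.weights[layer].T
    return gW, gb, delta
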