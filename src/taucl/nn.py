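"""A small NumPy 3D convolutional network with explicit backpropagation.

The network maps a 3D volume to a scalar through a stack of strided 3D
convolutions (im2col / GEMM implementation), a pointwise nonlinearity,
global average pooling, and a small dense head.  Every layer implements an
exact ``backward`` pass; backpropagating all the way to the input produces
the exact gradient of the scalar output with respect to every input voxel,
which is what gradient saliency maps are made of.

Everything is plain NumPy: the forward pass is a handful of matrix products
per layer, and the backward pass of a strided convolution is implemented as
k^3 strided-slice scatter-adds (no Python-level loops over voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters for the CL regressor.

    The default desk-scale architecture has three stride-2 convolution
    stages (8/16/32 channels, 3^3 kernels, ReLU) and a dense head on the
    flattened final feature map, so the head keeps one weight per spatial
    cell — position-specific parameters are what allow spatially focal
    attributions on template-space images (a global-average-pooling head,
    available as ``head_style="gap"``, is position-free and its saliency is
    inherently diffuse).  Training is RMSprop on mean squared error with
    early stopping on validation RMSE and learning-rate halving on plateau.
    """

    channels: tuple[int, ...] = (8, 16, 32)
    kernel_size: int = 3
    stride: int = 2
    activation: str = "relu"
    head_style: str = "flatten"
    dense_widths: tuple[int, ...] = (32,)
    learning_rate: float = 3e-3
    batch_size: int = 8
    max_epochs: int = 250
    patience: int = 30
    optimizer: str = "rmsprop"
    rmsprop_rho: float = 0.9
    weight_decay: float = 0.0
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 10
    min_learning_rate: float = 1e-4
    standardize_targets: bool = True
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValueError("need at least 2 convolution stages")
        if any(c <= 0 for c in self.channels) or any(w <= 0 for w in self.dense_widths):
            raise ValueError("all layer widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.activation not in ("relu", "softplus"):
            raise ValueError("activation must be 'relu' or 'softplus'")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is implemented")
        if self.head_style not in ("gap", "flatten"):
            raise ValueError("head_style must be 'gap' or 'flatten'")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution (cross-correlation) with stride and symmetric padding."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng, dtype) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k ** 3))  # He initialisation
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in, k, k, k)).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def _im2col(self, x: np.ndarray):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        sw = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        # sw: (B, C, D', H', W', k, k, k)
        out_shape = sw.shape[2:5]
        cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        return cols.reshape(x.shape[0], -1, self.c_in * k ** 3), out_shape, xp.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, out_shape, xp_shape = self._im2col(x)
        self._cols, self._out_shape, self._xp_shape = cols, out_shape, xp_shape
        self._x_shape = x.shape
        Wmat = self.params["W"].reshape(self.c_out, -1)
        out = cols @ Wmat.T + self.params["b"]
        return np.ascontiguousarray(
            out.reshape(x.shape[0], *out_shape, self.c_out).transpose(0, 4, 1, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B = dout.shape[0]
        k, s = self.k, self.stride
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(B, -1, self.c_out)
        Wmat = self.params["W"].reshape(self.c_out, -1)
        dW = np.einsum("bpo,bpc->oc", dflat, self._cols, optimize=True)
        self.grads = {"W": dW.reshape(self.params["W"].shape).astype(Wmat.dtype),
                      "b": dflat.sum(axis=(0, 1))}
        dcols = dflat @ Wmat  # (B, P, C*k^3)
        Do, Ho, Wo = self._out_shape
        dcols = dcols.reshape(B, Do, Ho, Wo, self.c_in, k, k, k).transpose(
            0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((B, self.c_in) + self._xp_shape[2:], dtype=dout.dtype)
        for a, b, c in product(range(k), repeat=3):
            dxp[:, :, a:a + s * Do:s, b:b + s * Ho:s, c:c + s * Wo:s] += \
                dcols[:, :, :, :, :, a, b, c]
        p = self.pad
        D, H, W = self._x_shape[2:]
        return dxp[:, :, p:p + D, p:p + H, p:p + W]


class Activation(Layer):
    def __init__(self, kind: str) -> None:
        super().__init__()
        self.kind = kind

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        return np.logaddexp(0.0, x)  # softplus

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return dout * (self._x > 0)
        return dout / (1.0 + np.exp(-self._x))


class GlobalAvgPool(Layer):
    """(B, C, D, H, W) -> (B, C) mean over the spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, D, H, W = self._shape
        return np.broadcast_to(
            dout[:, :, None, None, None], self._shape).copy() / (D * H * W)


class Flatten(Layer):
    """(B, C, D, H, W) -> (B, C*D*H*W); keeps position-specific weights
    downstream, which is what lets attribution stay spatially focal."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng, dtype) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_out, n_in)).astype(dtype),
                       "b": np.zeros(n_out, dtype=dtype)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"W": dout.T @ self._x, "b": dout.sum(axis=0)}
        return dout @ self.params["W"]


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """Sequential scalar-regression network over 3D volumes."""

    def __init__(self, layers: list[Layer], dtype=np.float32) -> None:
        self.layers = layers
        self.dtype = np.dtype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, D, H, W) -> predictions (B,) on the standardised scale."""
        h = np.ascontiguousarray(x[:, None], dtype=self.dtype)  # add channel axis
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); returns d(loss)/d(input voxels)."""
        g = np.asarray(dy, dtype=self.dtype)[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g[:, 0]  # drop channel axis

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Exact gradient of each scalar output w.r.t. its input voxels.

        x: (B, D, H, W) -> (B, D, H, W).  Each sample's gradient is
        independent of the others (the network has no cross-sample ops).
        """
        self.forward(x)
        return self.backward(np.ones(x.shape[0]))

    # -- parameter plumbing -------------------------------------------------
    def get_params(self) -> list[dict]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_params(self, params: list[dict]) -> None:
        for layer, p in zip(self.layers, params):
            for k in layer.params:
                layer.params[k] = p[k].copy()

    def n_params(self) -> int:
        return sum(int(v.size) for layer in self.layers for v in layer.params.values())


def conv_output_shape(input_shape, n_stages: int, k: int, s: int):
    """Spatial shape after ``n_stages`` stride-s convolutions (pad k//2)."""
    shape = tuple(int(n) for n in input_shape)
    p = k // 2
    for _ in range(n_stages):
        shape = tuple((n + 2 * p - k) // s + 1 for n in shape)
    return shape


def build_network(config: CNNConfig, rng: np.random.Generator,
                  input_shape=None) -> Network:
    """Assemble the conv encoder + pooling/flatten + dense head.

    ``head_style="gap"`` global-average-pools the last feature map (few
    parameters, position-free); ``"flatten"`` keeps one weight per spatial
    cell of the last feature map (needs ``input_shape``), giving the head
    position-specific parameters.
    """
    dtype = np.dtype(config.dtype)
    layers: list[Layer] = []
    c_prev = 1
    for c in config.channels:
        layers.append(Conv3D(c_prev, c, config.kernel_size, config.stride, rng, dtype))
        layers.append(Activation(config.activation))
        c_prev = c
    if config.head_style == "gap":
        layers.append(GlobalAvgPool())
    else:
        if input_shape is None:
            raise ValueError("flatten head needs the input grid shape")
        spatial = conv_output_shape(input_shape, len(config.channels),
                                    config.kernel_size, config.stride)
        layers.append(Flatten())
        c_prev = c_prev * int(np.prod(spatial))
    for w in config.dense_widths:
        layers.append(Dense(c_prev, w, rng, dtype))
        layers.append(Activation(config.activation))
        c_prev = w
    layers.append(Dense(c_prev, 1, rng, dtype))
    return Network(layers, dtype)


class RMSprop:
    """RMSprop with optional decoupled L2 weight decay.

    The running RMS of each gradient scales its step; weight decay is
    applied directly to the parameters (not through the RMS), so its
    strength does not depend on the gradient history.  Decay spreads weight
    across redundant informative voxels and shrinks weights that serve no
    loss, which makes input attributions more uniform within informative
    regions and weaker outside them.
    """

    def __init__(self, network: Network, lr: float, rho: float = 0.9,
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.network, self.lr, self.rho, self.eps = network, lr, rho, eps
        self.weight_decay = weight_decay
        self.cache = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                      for layer in network.layers]

    def step(self) -> None:
        for layer, sq in zip(self.network.layers, self.cache):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(p.dtype)
                sq[k] = self.rho * sq[k] + (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(sq[k]) + self.eps)
                if self.weight_decay > 0 and k == "W":
                    p -= self.lr * self.weight_decay * p
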