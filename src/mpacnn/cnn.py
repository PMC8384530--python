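"""A compact convolutional classifier with a pure-NumPy forward and backward pass.

The network follows the pattern (conv 3x3 -> ReLU -> 2x2 max pool) repeated per
conv stage, then flatten, a small dense head with dropout, and a softmax output.
Training minimizes the summed cross-entropy between softmax outputs and one-hot
labels, optionally with an L2 penalty (eta/2) * sum(w^2) on connection weights
(biases excluded).  Two trainers exist: RMSprop gradient descent (this module)
and the Marine Predators Algorithm acting on the flattened parameter vector
(:mod:`mpacnn.mpa_cnn`).

Images are (N, H, W) or (N, H, W, 1) float arrays; labels are (N, M) one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

PROB_EPS = 1e-12  # log(0) guard inside the cross-entropy


# ---------------------------------------------------------------------------
# architecture and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Static description of the classifier.

    Defaults give the full-scale network: three conv stages with 32/64/128
    output channels (3x3 kernels, stride 1, no padding), 2x2 max pooling after
    each, one dense hidden layer of 64 units with dropout 0.5, softmax over
    ``num_classes``.  Smaller configurations are used throughout the tests.
    """

    input_shape: tuple[int, int, int] = (227, 227, 1)
    conv_filters: tuple[int, ...] = (32, 64, 128)
    #: either one (h, w) pair shared by all conv stages, or one pair per stage
    conv_kernel: tuple = (3, 3)
    pool_window: tuple[int, int] = (2, 2)
    dense_units: tuple[int, ...] = (64,)
    num_classes: int = 2
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if len(self.conv_filters) == 0 or any(f < 1 for f in self.conv_filters):
            raise ValueError("conv_filters must be non-empty with counts >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        self.feature_shapes()  # raises if the spatial dims underflow

    def stage_kernels(self) -> list[tuple[int, int]]:
        """Spatial conv kernel per stage, broadcasting a single shared pair."""
        k = self.conv_kernel
        if isinstance(k[0], (tuple, list)):
            if len(k) != len(self.conv_filters):
                raise ValueError("per-stage conv_kernel list must match conv_filters")
            return [tuple(pair) for pair in k]
        return [tuple(k)] * len(self.conv_filters)

    def feature_shapes(self) -> list[tuple[int, int, int]]:
        """(H, W, C) after each conv+pool stage; validates no dimension underflow."""
        h, w, c = self.input_shape
        ph, pw = self.pool_window
        shapes = []
        for filters, (kh, kw) in zip(self.conv_filters, self.stage_kernels()):
            h, w = h - kh + 1, w - kw + 1
            if h < ph or w < pw:
                raise ValueError(
                    f"feature map {h}x{w} smaller than pool window {ph}x{pw}: "
                    f"input {self.input_shape} cannot support {len(self.conv_filters)} conv stages"
                )
            h, w = h // ph, w // pw
            c = filters
            shapes.append((h, w, c))
        return shapes

    def layer_shapes(self) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """Weight/bias shapes per trainable layer, conv stages first then dense."""
        shapes: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
        c_in = self.input_shape[2]
        for filters, (kh, kw) in zip(self.conv_filters, self.stage_kernels()):
            shapes.append(((kh, kw, c_in, filters), (filters,)))
            c_in = filters
        h, w, c = self.feature_shapes()[-1]
        width_in = h * w * c
        for units in (*self.dense_units, self.num_classes):
            shapes.append(((width_in, units), (units,)))
            width_in = units
        return shapes

    @property
    def n_parameters(self) -> int:
        return sum(int(np.prod(w)) + int(np.prod(b)) for w, b in self.layer_shapes())


@dataclass
class NetworkParams:
    """Per-layer weight tensors and bias vectors, ordered conv stages then dense."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def layer_count(self) -> int:
        return len(self.weights)

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights],
                             [b.copy() for b in self.biases])


def init_params(
    arch: ArchitectureSpec,
    rng: np.random.Generator,
    scheme: str = "he",
    bound: float = 1.0,
) -> NetworkParams:
    """Random initial parameters.

    ``"he"`` scales each weight tensor by sqrt(2 / fan_in) — the right scale for
    ReLU networks trained by gradient descent; biases start at zero.
    ``"uniform"`` draws every entry, biases included, from [-bound, bound],
    matching the box the metaheuristic searches.
    """
    weights, biases = [], []
    for w_shape, b_shape in arch.layer_shapes():
        fan_in = int(np.prod(w_shape[:-1]))
        if scheme == "he":
            weights.append(rng.standard_normal(w_shape) * np.sqrt(2.0 / fan_in))
            biases.append(np.zeros(b_shape))
        elif scheme == "uniform":
            weights.append(rng.uniform(-bound, bound, size=w_shape))
            biases.append(rng.uniform(-bound, bound, size=b_shape))
        else:
            raise ValueError(f"unknown init scheme {scheme!r}")
    return NetworkParams(weights, biases)


# ---------------------------------------------------------------------------
# layer operators
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x): negative activations become zero."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def _as_nhwc(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Normalize a feature map to (N, H, W, C); return it and the original ndim."""
    arr = np.asarray(x, dtype=float)
    ndim = arr.ndim
    if ndim == 2:
        arr = arr[None, :, :, None]
    elif ndim == 3:
        arr = arr[None]
    elif ndim != 4:
        raise ValueError(f"expected 2-D, 3-D or 4-D feature map, got ndim={ndim}")
    return arr, ndim


def max_pool(x: np.ndarray, window: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Non-overlapping max pooling: each output cell is the max of its block.

    Stride equals the window; trailing rows/columns that do not fill a complete
    block are dropped (floor division of the spatial dims).
    """
    arr, ndim = _as_nhwc(x)
    ph, pw = int(window[0]), int(window[1])
    n, h, w, c = arr.shape
    if h < ph or w < pw:
        raise ValueError(f"spatial dims {h}x{w} smaller than pool window {ph}x{pw}")
    ho, wo = h // ph, w // pw
    blocks = arr[:, : ho * ph, : wo * pw, :].reshape(n, ho, ph, wo, pw, c)
    out = blocks.max(axis=(2, 4))
    if ndim == 2:
        return out[0, :, :, 0]
    if ndim == 3:
        return out[0]
    return out


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exponential normalization of scores into probabilities.

    Overflow-safe via the shift invariance softmax(f + c) == softmax(f).
    """
    f = np.asarray(scores, dtype=float)
    shifted = f - f.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def dropout(
    x: np.ndarray,
    rate: float,
    training: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomly zero units during training; identity at inference.

    Uses the inverted convention: survivors are scaled by 1/(1-rate) so the
    expectation of the output equals the input and inference needs no rescaling.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
    arr = np.asarray(x, dtype=float)
    if not training or rate == 0.0:
        return arr.copy()
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    mask = rng.random(arr.shape) >= rate
    return arr * mask / (1.0 - rate)


# ---------------------------------------------------------------------------
# losses and costs
# ---------------------------------------------------------------------------

def cross_entropy(z: np.ndarray, d: np.ndarray) -> float:
    """Summed cross-entropy  sum_j sum_i -d_ji log z_ji  over samples and classes.

    ``z`` holds predicted class probabilities per row, ``d`` one-hot labels.
    Probabilities are clamped at ``PROB_EPS`` so a confident wrong prediction
    yields a large finite loss rather than an exception.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    if z.shape != d.shape:
        raise ValueError(f"shape mismatch: z {z.shape} vs d {d.shape}")
    return float(-(d * np.log(np.clip(z, PROB_EPS, None))).sum())


def weight_norm_sq(params: NetworkParams) -> float:
    """Sum of squared connection weights (biases excluded)."""
    return float(sum((w ** 2).sum() for w in params.weights))


def regularized_loss(z: np.ndarray, d: np.ndarray, params: NetworkParams, eta: float) -> float:
    """Cross-entropy plus the L2 weight penalty (eta/2) * sum of squared weights."""
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta}")
    return cross_entropy(z, d) + 0.5 * eta * weight_norm_sq(params)


def mse_cost(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean-per-sample squared error  E = (1/T) sum_i sum_j (d_ji - o_ji)^2.

    T is the sample count (first axis); the inner sum runs over the k network
    outputs, so a constant (0.5, 0.5) predictor on one-hot 2-class targets
    scores exactly 0.5 regardless of T.
    """
    o = np.asarray(outputs, dtype=float)
    d = np.asarray(targets, dtype=float)
    if o.shape != d.shape:
        raise ValueError(f"shape mismatch: outputs {o.shape} vs targets {d.shape}")
    t = o.shape[0]
    if t == 0:
        raise ValueError("empty output matrix")
    return float(((d - o) ** 2).sum() / t)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _conv_cols(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """im2col: (N,H,W,C) -> (N, Ho, Wo, kh*kw*C) patch matrix."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N,Ho,Wo,C,kh,kw)
    v = v.transpose(0, 1, 2, 4, 5, 3)                  # (N,Ho,Wo,kh,kw,C)
    n, ho, wo = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n, ho, wo, -1)

def _conv_forward(x, w, b):
    kh, kw, c_in, c_out = w.shape
    cols = _conv_cols(x, kh, kw)
    out = cols @ w.reshape(-1, c_out) + b
    return out, cols


def _conv_backward(dout, cols, w, x_shape):
    kh, kw, c_in, c_out = w.shape
    n, ho, wo, _ = dout.shape
    dw = (cols.reshape(-1, kh * kw * c_in).T @ dout.reshape(-1, c_out)).reshape(w.shape)
    db = dout.sum(axis=(0, 1, 2))
    dcols = (dout @ w.reshape(-1, c_out).T).reshape(n, ho, wo, kh, kw, c_in)
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
    return dx, dw, db


def _pool_forward(x, window):
    ph, pw = window
    n, h, w, c = x.shape
    ho, wo = h // ph, w // pw
    blocks = x[:, : ho * ph, : wo * pw, :].reshape(n, ho, ph, wo, pw, c)
    blocks = blocks.transpose(0, 1, 3, 2, 4, 5).reshape(n, ho, wo, ph * pw, c)
    idx = blocks.argmax(axis=3)
    out = np.take_along_axis(blocks, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _pool_backward(dout, idx, x_shape, window):
    ph, pw = window
    n, h, w, c = x_shape
    ho, wo = h // ph, w // pw
    dblocks = np.zeros((n, ho, wo, ph * pw, c))
    np.put_along_axis(dblocks, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = np.zeros(x_shape)
    dx[:, : ho * ph, : wo * pw, :] = (
        dblocks.reshape(n, ho, wo, ph, pw, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, ho * ph, wo * pw, c)
    )
    return dx


def _images_to_nhwc(images: np.ndarray, arch: ArchitectureSpec) -> np.ndarray:
    """Normalize classifier input to (N, H, W, C): accepts (H,W), (N,H,W), (N,H,W,C)."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        x = x[None, :, :, None]
    elif x.ndim == 3:
        x = x[:, :, :, None]
    elif x.ndim != 4:
        raise ValueError(f"expected image stack with 2-4 dims, got ndim={x.ndim}")
    if x.shape[3] != arch.input_shape[2]:
        raise ValueError(f"channel count {x.shape[3]} != input_shape {arch.input_shape}")
    return x


def _forward_impl(params, images, arch, training, rng):
    x = _images_to_nhwc(images, arch)
    if x.shape[1:3] != arch.input_shape[:2]:
        raise ValueError(f"images {x.shape[1:3]} do not match input_shape {arch.input_shape[:2]}")
    caches = []
    n_conv = len(arch.conv_filters)
    for li in range(n_conv):
        pre, cols = _conv_forward(x, params.weights[li], params.biases[li])
        act = relu(pre)
        pooled, idx = _pool_forward(act, arch.pool_window)
        caches.append(("conv", x.shape, cols, pre, act.shape, idx))
        x = pooled
    flat_shape = x.shape
    x = x.reshape(x.shape[0], -1)
    n_dense = len(arch.dense_units)
    for di in range(n_dense):
        li = n_conv + di
        pre = x @ params.weights[li] + params.biases[li]
        act = relu(pre)
        if training and arch.dropout_rate > 0.0:
            mask = rng.random(act.shape) >= arch.dropout_rate
            dropped = act * mask / (1.0 - arch.dropout_rate)
        else:
            mask = None
            dropped = act
        caches.append(("dense", x, pre, mask))
        x = dropped
    li = n_conv + n_dense
    logits = x @ params.weights[li] + params.biases[li]
    caches.append(("out", x))
    probs = softmax(logits, axis=1)
    return probs, (caches, flat_shape)


def forward(
    params: NetworkParams,
    images: np.ndarray,
    arch: ArchitectureSpec,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Run the classifier; returns an (N, num_classes) probability matrix.

    Inference mode (default) is a pure deterministic function of
    ``(params, images)``; training mode applies dropout and requires ``rng``.
    """
    if training and arch.dropout_rate > 0.0 and rng is None:
        raise ValueError("training-mode forward requires an rng for dropout")
    probs, _ = _forward_impl(params, images, arch, training, rng)
    return probs


def _backward_impl(params, arch, probs, labels, cache, eta):
    """Gradient of cross_entropy(probs, labels) + (eta/2)||w||^2 w.r.t. params."""
    caches, flat_shape = cache
    dweights = [None] * params.layer_count
    dbiases = [None] * params.layer_count
    dlogits = probs - labels  # summed-CE + softmax gradient
    n_conv = len(arch.conv_filters)
    n_dense = len(arch.dense_units)

    kind_out = caches[-1]
    li = n_conv + n_dense
    x_out = kind_out[1]
    dweights[li] = x_out.T @ dlogits
    dbiases[li] = dlogits.sum(axis=0)
    dx = dlogits @ params.weights[li].T

    for di in reversed(range(n_dense)):
        li = n_conv + di
        _, x_in, pre, mask = caches[li]
        if mask is not None:
            dx = dx * mask / (1.0 - arch.dropout_rate)
        dpre = dx * (pre > 0)
        dweights[li] = x_in.T @ dpre
        dbiases[li] = dpre.sum(axis=0)
        dx = dpre @ params.weights[li].T

    dx = dx.reshape(flat_shape)
    for li in reversed(range(n_conv)):
        _, x_shape, cols, pre, act_shape, idx = caches[li]
        dact = _pool_backward(dx, idx, act_shape, arch.pool_window)
        dpre = dact * (pre > 0)
        dx, dw, db = _conv_backward(dpre, cols, params.weights[li], x_shape)
        dweights[li] = dw
        dbiases[li] = db

    if eta > 0:
        for li in range(params.layer_count):
            dweights[li] = dweights[li] + eta * params.weights[li]
    return dweights, dbiases


def loss_and_grad(
    params: NetworkParams,
    images: np.ndarray,
    labels: np.ndarray,
    arch: ArchitectureSpec,
    eta: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Regularized loss and its exact gradient on one batch."""
    probs, cache = _forward_impl(params, images, arch, training, rng)
    loss = regularized_loss(probs, labels, params, eta)
    dw, db = _backward_impl(params, arch, probs, np.asarray(labels, dtype=float), cache, eta)
    return loss, dw, db


# ---------------------------------------------------------------------------
# RMSprop trainer
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: NetworkParams
    history: list[float] = field(default_factory=list)


def train_rmsprop(
    arch: ArchitectureSpec,
    images: np.ndarray,
    labels: np.ndarray,
    iterations: int = 200,
    eta: float = 1e-4,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    decay: float = 0.9,
    epsilon: float = 1e-8,
    seed: int | None = None,
    init: NetworkParams | None = None,
) -> TrainResult:
    """Train by RMSprop on the regularized cross-entropy.

    Each iteration samples one minibatch (without replacement within the
    iteration), takes an RMSprop step, and records the full-training-set
    regularized loss.  The parameters with the lowest recorded loss are
    returned, so the final loss never exceeds the initial one.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    if labels.ndim != 2 or labels.shape[0] != images.shape[0]:
        raise ValueError("labels must be (N, num_classes) one-hot matching images")

    rng = np.random.default_rng(seed)
    params = init.copy() if init is not None else init_params(arch, rng, scheme="he")
    sq_w = [np.zeros_like(w) for w in params.weights]
    sq_b = [np.zeros_like(b) for b in params.biases]
    n = images.shape[0]
    bs = min(batch_size, n)

    def full_loss(p: NetworkParams) -> float:
        probs = forward(p, images, arch, training=False)
        return regularized_loss(probs, labels, p, eta)

    best = params.copy()
    best_loss = full_loss(params)
    history = [best_loss]
    for _ in range(iterations):
        take = rng.choice(n, size=bs, replace=False)
        _, dw, db = loss_and_grad(params, images[take], labels[take], arch,
                                  eta=eta, training=arch.dropout_rate > 0.0, rng=rng)
        for li in range(params.layer_count):
            sq_w[li] = decay * sq_w[li] + (1 - decay) * dw[li] ** 2
            sq_b[li] = decay * sq_b[li] + (1 - decay) * db[li] ** 2
            params.weights[li] -= learning_rate * dw[li] / (np.sqrt(sq_w[li]) + epsilon)
            params.biases[li] -= learning_rate * db[li] / (np.sqrt(sq_b[li]) + epsilon)
        cur = full_loss(params)
        history.append(cur)
        if cur < best_loss:
            best_loss = cur
            best = params.copy()
    return TrainResult(params=best, history=history)


def predict_labels(params: NetworkParams, images: np.ndarray, arch: ArchitectureSpec) -> np.ndarray:
    """Hard class predictions (argmax of the softmax output)."""
    return forward(params, images, arch, training=False).argmax(axis=1)


def one_hot(labels: Sequence[int], num_classes: int) -> np.ndarray:
    """Integer labels -> (N, num_classes) one-hot float matrix."""
    y = np.asarray(labels, dtype=int)
    if y.size and (y.min() < 0 or y.max() >= num_classes):
        raise ValueError("labels out of range for num_classes")
    out = np.zeros((y.shape[0], num_classes))
    out[np.arange(y.shape[0]), y] = 1.0
    return out
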