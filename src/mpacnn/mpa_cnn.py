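"""Coupling the Marine Predators Algorithm to the convolutional classifier.

The optimizer sees the network as a flat real vector.  Three encodings exist:

* ``weights-only`` — the vector is the layer-major concatenation of every
  weight tensor and bias vector; MPA searches a symmetric box per entry.
* ``hyperparams-only`` — the vector holds 10 integer-coded architecture
  hyperparameters; each candidate is decoded, briefly pre-trained with the
  RMSprop baseline, and scored.
* ``joint`` — hyperparameter coordinates first, then weights for the *base*
  architecture (decoded weight-shaped candidates are only meaningful when the
  decoded architecture matches the base one, so joint mode keeps architecture
  coordinates that only tune dropout/batch codes).

The training cost is either the per-sample summed squared error between the
softmax outputs and the one-hot targets (default) or the misclassification
rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import mpa
from .cnn import (
    ArchitectureSpec,
    NetworkParams,
    forward,
    init_params,
    mse_cost,
    one_hot,
    train_rmsprop,
)

#: coordinate map for the 10 integer-coded hyperparameters:
#: (name, lower bound, upper bound); every lower bound is >= 2
HYPER_COORDS: tuple[tuple[str, int, int], ...] = (
    ("conv_filters_1", 2, 16),
    ("conv_filters_2", 2, 16),
    ("conv_filters_3", 2, 16),
    ("conv_kernel_1", 2, 7),
    ("conv_kernel_2", 2, 7),
    ("conv_kernel_3", 2, 7),
    ("pool_window", 2, 3),
    ("dense_units", 2, 64),
    ("dropout_code", 2, 10),   # dropout rate = code / 20  ->  0.10 .. 0.50
    ("batch_size", 2, 32),
)


@dataclass(frozen=True)
class EncodingSpec:
    """How a flat prey vector maps onto the classifier.

    ``weight_bound`` is the half-width of the symmetric search box for each
    weight entry; hyperparameter coordinates use the integer bounds of
    ``HYPER_COORDS``.
    """

    mode: str = "weights-only"  # weights-only | hyperparams-only | joint
    weight_bound: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("weights-only", "hyperparams-only", "joint"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.weight_bound <= 0:
            raise ValueError("weight_bound must be positive")

    def dimension(self, arch: ArchitectureSpec) -> int:
        n_hyper = len(HYPER_COORDS)
        n_weights = arch.n_parameters
        if self.mode == "weights-only":
            return n_weights
        if self.mode == "hyperparams-only":
            return n_hyper
        return n_hyper + n_weights

    def bounds(self, arch: ArchitectureSpec) -> tuple[np.ndarray, np.ndarray]:
        lows, highs = [], []
        if self.mode in ("hyperparams-only", "joint"):
            lows.extend(lo for _, lo, _ in HYPER_COORDS)
            highs.extend(hi for _, _, hi in HYPER_COORDS)
        if self.mode in ("weights-only", "joint"):
            nw = arch.n_parameters
            lows.extend([-self.weight_bound] * nw)
            highs.extend([self.weight_bound] * nw)
        return np.asarray(lows, dtype=float), np.asarray(highs, dtype=float)


# ---------------------------------------------------------------------------
# flat-vector plumbing
# ---------------------------------------------------------------------------

def flatten_params(params: NetworkParams) -> np.ndarray:
    """Layer-major concatenation: layer 1 weights, layer 1 biases, layer 2 ..."""
    pieces = []
    for w, b in zip(params.weights, params.biases):
        pieces.append(w.ravel())
        pieces.append(b.ravel())
    return np.concatenate(pieces)


def unflatten_params(vec: np.ndarray, arch: ArchitectureSpec) -> NetworkParams:
    """Exact inverse of :func:`flatten_params` for the given architecture."""
    vec = np.asarray(vec, dtype=float)
    expected = arch.n_parameters
    if vec.ndim != 1 or vec.shape[0] != expected:
        raise ValueError(f"flat vector length {vec.shape} != parameter count {expected}")
    weights, biases = [], []
    offset = 0
    for w_shape, b_shape in arch.layer_shapes():
        wn = int(np.prod(w_shape))
        weights.append(vec[offset : offset + wn].reshape(w_shape).copy())
        offset += wn
        bn = int(np.prod(b_shape))
        biases.append(vec[offset : offset + bn].reshape(b_shape).copy())
        offset += bn
    return NetworkParams(weights, biases)


def decode_hyperparams(vec: np.ndarray, base: ArchitectureSpec) -> tuple[ArchitectureSpec, int]:
    """Decode the 10-coordinate hyperparameter block into an architecture.

    Each coordinate is rounded to the nearest integer and clamped into its
    bounds.  Conv stages whose kernel or pool window would underflow the
    spatial dimensions of ``base.input_shape`` are dropped from the tail, so
    every decoded vector admits a forward pass.  Returns the architecture and
    the decoded batch size.
    """
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (len(HYPER_COORDS),):
        raise ValueError(f"expected {len(HYPER_COORDS)} hyper coordinates, got {vec.shape}")
    codes = {}
    for (name, lo, hi), value in zip(HYPER_COORDS, vec):
        codes[name] = int(np.clip(np.rint(value), lo, hi))
    pool = codes["pool_window"]
    filters = [codes[f"conv_filters_{i}"] for i in (1, 2, 3)]
    kernels = [codes[f"conv_kernel_{i}"] for i in (1, 2, 3)]
    # keep the longest conv prefix that still admits a forward pass; each
    # kernel must stay strictly smaller than its stage's spatial input
    h, w = base.input_shape[:2]
    kept = 0
    for k in kernels:
        nh, nw = h - k + 1, w - k + 1
        if k >= min(h, w) or nh < pool or nw < pool:
            break
        h, w = nh // pool, nw // pool
        kept += 1
        if h < 1 or w < 1:
            break
    if kept == 0:
        raise ValueError(f"input {base.input_shape} too small for any decoded conv stage")
    arch = ArchitectureSpec(
        input_shape=base.input_shape,
        conv_filters=tuple(filters[:kept]),
        conv_kernel=tuple((k, k) for k in kernels[:kept]),
        pool_window=(pool, pool),
        dense_units=(codes["dense_units"],),
        num_classes=base.num_classes,
        dropout_rate=codes["dropout_code"] / 20.0,
    )
    return arch, codes["batch_size"]


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def cnn_cost(
    vec: np.ndarray,
    images: np.ndarray,
    labels: np.ndarray,
    arch: ArchitectureSpec,
    cost_kind: str = "mse",
) -> float:
    """Score one weight vector: build the network, run inference, measure error.

    ``cost_kind="mse"`` returns (1/T) sum_i sum_j (d_ji - o_ji)^2 on the softmax
    outputs; ``"error_rate"`` returns the misclassification fraction.
    Deterministic given (vec, data).
    """
    if cost_kind not in ("mse", "error_rate"):
        raise ValueError(f"unknown cost kind {cost_kind!r}")
    params = unflatten_params(vec, arch)
    probs = forward(params, images, arch, training=False)
    targets = np.asarray(labels, dtype=float)
    if cost_kind == "mse":
        return mse_cost(probs, targets)
    pred = probs.argmax(axis=1)
    true = targets.argmax(axis=1)
    return float(np.mean(pred != true))


@dataclass
class MPATrainResult:
    params: NetworkParams
    arch: ArchitectureSpec
    best_cost: float
    history: list[float]
    batch_size: int | None = None


def _hyper_objective(images, labels, base, cost_kind, pretrain_iters, seed):
    def objective(vec: np.ndarray) -> float:
        arch, batch = decode_hyperparams(vec[: len(HYPER_COORDS)], base)
        result = train_rmsprop(arch, images, labels, iterations=pretrain_iters,
                               batch_size=batch, seed=seed)
        return cnn_cost(flatten_params(result.params), images, labels, arch, cost_kind)
    return objective


def train_with_mpa(
    arch: ArchitectureSpec,
    images: np.ndarray,
    labels: np.ndarray,
    mpa_cfg: mpa.MPAConfig | None = None,
    encoding: EncodingSpec = EncodingSpec(),
    cost_kind: str = "mse",
    n: int = 100,
    max_iter: int = 200,
    seed: int | None = None,
    pretrain_iters: int = 5,
) -> MPATrainResult:
    """Train the classifier by running MPA on the chosen encoding.

    In weights-only mode (default) the prey are complete flat weight vectors
    and the cost is pure inference — no gradients anywhere.  The returned
    history is the optimizer's best-so-far cost per iteration and is monotone
    non-increasing.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    d = encoding.dimension(arch)
    if d == 0:
        raise ValueError("zero-dimensional encoding: nothing to optimize")
    lows, highs = encoding.bounds(arch)
    if mpa_cfg is None:
        mpa_cfg = mpa.MPAConfig(d=d, x_min=lows, x_max=highs, n=n,
                                max_iter=max_iter, seed=seed)
    elif mpa_cfg.d != d:
        raise ValueError(f"mpa_cfg dimension {mpa_cfg.d} != encoding dimension {d}")

    if encoding.mode == "weights-only":
        objective = lambda vec: cnn_cost(vec, images, labels, arch, cost_kind)
        result = mpa.optimize(objective, mpa_cfg)
        return MPATrainResult(params=unflatten_params(result.best_position, arch),
                              arch=arch, best_cost=result.best_cost,
                              history=result.history)

    if encoding.mode == "hyperparams-only":
        objective = _hyper_objective(images, labels, arch, cost_kind, pretrain_iters, seed)
        result = mpa.optimize(objective, mpa_cfg)
        best_arch, batch = decode_hyperparams(result.best_position, arch)
        trained = train_rmsprop(best_arch, images, labels, iterations=pretrain_iters,
                                batch_size=batch, seed=seed)
        return MPATrainResult(params=trained.params, arch=best_arch,
                              best_cost=result.best_cost, history=result.history,
                              batch_size=batch)

    # joint: hyper block tunes dropout/batch codes; weight block is scored on
    # the base architecture
    n_hyper = len(HYPER_COORDS)

    def objective(vec: np.ndarray) -> float:
        return cnn_cost(vec[n_hyper:], images, labels, arch, cost_kind)

    result = mpa.optimize(objective, mpa_cfg)
    _, batch = decode_hyperparams(result.best_position[:n_hyper], arch)
    return MPATrainResult(params=unflatten_params(result.best_position[n_hyper:], arch),
                          arch=arch, best_cost=result.best_cost,
                          history=result.history, batch_size=batch)


def labels_to_targets(labels: Sequence[int], num_classes: int) -> np.ndarray:
    """Convenience alias: integer class labels to one-hot target rows."""
    return one_hot(labels, num_classes)


def teacher_student_recovery(
    seed: int,
    n_data: int = 40,
    n: int = 25,
    max_iter: int = 300,
) -> dict:
    """Weights-only recovery experiment against a frozen random teacher.

    A tiny (20-parameter) network with random weights *and* biases drawn from
    the MPA search box labels ``n_data`` random 6x6 images with its softmax
    outputs; MPA then trains a student of the same architecture from scratch on
    those targets.  Because the teacher lies inside the search box the optimal
    cost is zero, so the ratio of the final cost to the initial population's
    best cost measures pure optimization power.  The teacher and data use an
    RNG stream independent of the optimizer's.
    """
    arch = ArchitectureSpec(input_shape=(6, 6, 1), conv_filters=(1,),
                            dense_units=(), num_classes=2, dropout_rate=0.0)
    teacher_rng = np.random.default_rng(100_000 + seed)
    teacher = init_params(arch, teacher_rng, scheme="uniform", bound=1.0)
    x = teacher_rng.random((n_data, 6, 6))
    targets = forward(teacher, x, arch)
    result = train_with_mpa(arch, x, targets, n=n, max_iter=max_iter, seed=seed)
    initial_best = result.history[0]
    return {
        "n_parameters": arch.n_parameters,
        "initial_best_cost": float(initial_best),
        "final_cost": float(result.best_cost),
        "cost_ratio": float(result.best_cost / initial_best),
    }
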