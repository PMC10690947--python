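"""The graph frequency-attention convolutional classifier.

Architecture: attention-weighted node features pass through two
graph-convolution layers

    H^(l) = sigma( A_hat @ H^(l-1) @ W^(l) ),       A_hat = D~^{-1/2} (A+I) D~^{-1/2}

whose node embeddings are flattened (row-major) into an hourglass-shaped
fully connected head (wide-narrow-wide hidden layers) followed by a
two-unit logistic output, one score per class in [0, 1].  Training
minimizes the mean squared error between the scores and one-hot targets,
so the network is small enough for exact analytic gradients, implemented
here directly in NumPy and verified against central differences in the
test suite.

Class order is fixed: index 0 = "responsive" (the positive class),
index 1 = "resistant".  Argmax prediction breaks ties toward responsive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .graph import GraphSample

CLASS_ORDER: tuple[str, str] = ("responsive", "resistant")
POSITIVE_CLASS = "responsive"


# ---------------------------------------------------------------------------
# activations


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(z.dtype)


def _tanh_grad(z: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(z) ** 2


def _identity(z: np.ndarray) -> np.ndarray:
    return z


def _one(z: np.ndarray) -> np.ndarray:
    return np.ones_like(z)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "identity": (_identity, _one),
}


def logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ArchConfig:
    """Network dimensions.

    Defaults give the stack 1024 -> 64 -> 32 graph features per node, a
    (19*32) -> 128 -> 32 -> 128 hourglass head and a 2-unit output.
    """

    n_nodes: int = 19
    feature_dim: int = 1024
    gcn_dims: tuple[int, ...] = (64, 32)
    dense_dims: tuple[int, ...] = (128, 32, 128)
    n_classes: int = 2
    activation: str = "relu"
    readout: str = "flatten"  # or 'mean'

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.readout not in ("flatten", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")

    @property
    def readout_dim(self) -> int:
        last = self.gcn_dims[-1] if self.gcn_dims else self.feature_dim
        return self.n_nodes * last if self.readout == "flatten" else last


@dataclass
class ModelParams:
    """All trainable weights.

    gcn_weights[l] has shape (in_dim, out_dim); graph layers carry no bias.
    dense_W / dense_b cover the hourglass hidden layers plus the output
    layer (the last entry).
    """

    gcn_weights: list[np.ndarray]
    dense_W: list[np.ndarray]
    dense_b: list[np.ndarray]
    arch: ArchConfig
    seed: int | None = None

    def copy(self) -> "ModelParams":
        return ModelParams(
            gcn_weights=[w.copy() for w in self.gcn_weights],
            dense_W=[w.copy() for w in self.dense_W],
            dense_b=[b.copy() for b in self.dense_b],
            arch=self.arch,
            seed=self.seed,
        )

    # flat-vector round trip, used by finite-difference checks
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.gcn_weights]
            + [w.ravel() for w in self.dense_W]
            + [b.ravel() for b in self.dense_b]
        )

    def from_vector(self, vec: np.ndarray) -> "ModelParams":
        out = self.copy()
        pos = 0
        for group in (out.gcn_weights, out.dense_W, out.dense_b):
            for i, arr in enumerate(group):
                group[i] = vec[pos : pos + arr.size].reshape(arr.shape)
                pos += arr.size
        if pos != vec.size:
            raise ValueError("vector size does not match parameter count")
        return out


def init_params(arch: ArchConfig, seed: int) -> ModelParams:
    """Glorot-uniform weights, zero biases, deterministic in the seed."""
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    gcn_weights = []
    d = arch.feature_dim
    for out_dim in arch.gcn_dims:
        gcn_weights.append(glorot(d, out_dim))
        d = out_dim
    dense_W, dense_b = [], []
    d = arch.readout_dim
    for out_dim in (*arch.dense_dims, arch.n_classes):
        dense_W.append(glorot(d, out_dim))
        dense_b.append(np.zeros(out_dim))
        d = out_dim
    return ModelParams(gcn_weights=gcn_weights, dense_W=dense_W,
                       dense_b=dense_b, arch=arch, seed=seed)


# ---------------------------------------------------------------------------
# forward


@dataclass(frozen=True)
class ClassScores:
    """Per-class scores in [0, 1]; argmax prediction, ties -> responsive."""

    values: np.ndarray  # ordered per CLASS_ORDER

    @property
    def predicted_label(self) -> str:
        return CLASS_ORDER[int(np.argmax(self.values))]

    @property
    def positive_score(self) -> float:
        return float(self.values[CLASS_ORDER.index(POSITIVE_CLASS)])


@dataclass
class LayerActivations:
    """Intermediate quantities of one forward pass (batch leading axis)."""

    H: list[np.ndarray]          # H[0] = attended X, then per GCN layer
    P: list[np.ndarray]          # P[l] = A_hat @ H[l] (pre-weight products)
    Z_gcn: list[np.ndarray]      # pre-activations of GCN layers
    readout: np.ndarray
    dense_Z: list[np.ndarray]    # pre-activations incl. output layer
    dense_A: list[np.ndarray]    # post-activations of hidden dense layers
    scores: np.ndarray           # (B, n_classes), logistic outputs


def gcn_layer(H_prev: np.ndarray, A_hat: np.ndarray, W: np.ndarray,
              sigma: str | Callable = "relu") -> np.ndarray:
    """One graph convolution: sigma(A_hat @ H_prev @ W), elementwise sigma."""
    act = ACTIVATIONS[sigma][0] if isinstance(sigma, str) else sigma
    if H_prev.shape[-1] != W.shape[0]:
        raise ValueError(
            f"feature dim {H_prev.shape[-1]} does not match W rows {W.shape[0]}"
        )
    if A_hat.shape[-1] != H_prev.shape[-2]:
        raise ValueError("adjacency order does not match node count")
    return act(A_hat @ H_prev @ W)


def forward_batch(X: np.ndarray, A: np.ndarray, params: ModelParams,
                  AX: np.ndarray | None = None) -> LayerActivations:
    """Batched forward pass.

    X : (B, n, d) node features, A : (B, n, n) normalized adjacencies.
    AX optionally carries the precomputed A @ X product (it is constant
    across training epochs, so callers hoist it out of the epoch loop).
    """
    act, _ = ACTIVATIONS[params.arch.activation]
    H = [X]
    P: list[np.ndarray] = []
    Z_gcn: list[np.ndarray] = []
    cur = X
    for l, W in enumerate(params.gcn_weights):
        pre = AX if (l == 0 and AX is not None) else A @ cur
        z = pre @ W
        cur = act(z)
        P.append(pre)
        Z_gcn.append(z)
        H.append(cur)
    if params.arch.readout == "flatten":
        f = cur.reshape(cur.shape[0], -1)
    else:
        f = cur.mean(axis=1)
    dense_Z, dense_A = [], []
    a = f
    for W, b in zip(params.dense_W[:-1], params.dense_b[:-1]):
        z = a @ W + b
        a = act(z)
        dense_Z.append(z)
        dense_A.append(a)
    z_out = a @ params.dense_W[-1] + params.dense_b[-1]
    dense_Z.append(z_out)
    scores = logistic(z_out)
    return LayerActivations(H=H, P=P, Z_gcn=Z_gcn, readout=f,
                            dense_Z=dense_Z, dense_A=dense_A, scores=scores)


def forward(sample: GraphSample, params: ModelParams
            ) -> tuple[ClassScores, LayerActivations]:
    """Single-sample forward pass."""
    cache = forward_batch(sample.X[None], sample.adjacency.A_hat[None], params)
    return ClassScores(values=cache.scores[0]), cache


# ---------------------------------------------------------------------------
# loss and gradients


def one_hot(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """One-hot targets in CLASS_ORDER; accepts label strings or indices."""
    if len(labels) and isinstance(labels[0], str):
        idx = np.array([CLASS_ORDER.index(l) for l in labels])
    else:
        idx = np.asarray(labels, dtype=int)
    out = np.zeros((idx.size, len(CLASS_ORDER)))
    out[np.arange(idx.size), idx] = 1.0
    return out


def mse_loss(scores: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error over all batch entries and classes."""
    return float(np.mean((scores - targets) ** 2))


@dataclass
class Gradients:
    gcn_weights: list[np.ndarray]
    dense_W: list[np.ndarray]
    dense_b: list[np.ndarray]

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [g.ravel() for g in self.gcn_weights]
            + [g.ravel() for g in self.dense_W]
            + [g.ravel() for g in self.dense_b]
        )


def _stack(batch: Sequence[GraphSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.X for s in batch])
    A = np.stack([s.adjacency.A_hat for s in batch])
    return X, A


def gradients(batch: Sequence[GraphSample] | tuple[np.ndarray, np.ndarray],
              targets: np.ndarray, params: ModelParams,
              AX: np.ndarray | None = None,
              ) -> tuple[Gradients, float]:
    """Exact gradients of the batch-averaged MSE loss.

    ``batch`` is either a sequence of graph samples or a pre-stacked
    ``(X, A)`` pair; ``targets`` are one-hot rows aligned to the batch.
    Returns the gradient structure and the loss value.
    """
    if isinstance(batch, tuple):
        X, A = batch
    else:
        if len(batch) == 0:
            raise ValueError("empty batch")
        X, A = _stack(batch)
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (X.shape[0], params.arch.n_classes):
        raise ValueError(
            f"targets shape {targets.shape} does not match "
            f"(batch={X.shape[0]}, classes={params.arch.n_classes})"
        )

    cache = forward_batch(X, A, params, AX=AX)
    _, act_grad = ACTIVATIONS[params.arch.activation]
    B = X.shape[0]
    scores = cache.scores
    loss = mse_loss(scores, targets)

    # output layer: logistic + MSE
    d_scores = 2.0 * (scores - targets) / scores.size
    dz = d_scores * scores * (1.0 - scores)
    dW_dense = [np.zeros_like(w) for w in params.dense_W]
    db_dense = [np.zeros_like(b) for b in params.dense_b]
    a_prev = cache.dense_A[-1] if cache.dense_A else cache.readout
    dW_dense[-1] = a_prev.T @ dz
    db_dense[-1] = dz.sum(axis=0)
    da = dz @ params.dense_W[-1].T

    for l in range(len(params.dense_W) - 2, -1, -1):
        dzl = da * act_grad(cache.dense_Z[l])
        a_in = cache.dense_A[l - 1] if l > 0 else cache.readout
        dW_dense[l] = a_in.T @ dzl
        db_dense[l] = dzl.sum(axis=0)
        da = dzl @ params.dense_W[l].T

    # back through the readout
    n_nodes = params.arch.n_nodes
    last_dim = cache.H[-1].shape[-1]
    if params.arch.readout == "flatten":
        dH = da.reshape(B, n_nodes, last_dim)
    else:
        dH = np.broadcast_to(da[:, None, :] / n_nodes,
                             (B, n_nodes, last_dim)).copy()

    # back through GCN layers (A_hat is symmetric, so A^T = A)
    dW_gcn = [np.zeros_like(w) for w in params.gcn_weights]
    for l in range(len(params.gcn_weights) - 1, -1, -1):
        dzl = dH * act_grad(cache.Z_gcn[l])
        dW_gcn[l] = np.einsum("bni,bnj->ij", cache.P[l], dzl)
        if l > 0:
            dH = A @ (dzl @ params.gcn_weights[l].T)

    return Gradients(gcn_weights=dW_gcn, dense_W=dW_dense, dense_b=db_dense), loss


def sgd_step(params: ModelParams, grads: Gradients, lr: float) -> None:
    """In-place SGD update."""
    for w, g in zip(params.gcn_weights, grads.gcn_weights):
        w -= lr * g
    for w, g in zip(params.dense_W, grads.dense_W):
        w -= lr * g
    for b, g in zip(params.dense_b, grads.dense_b):
        b -= lr * g


# -- persistence ------------------------------------------------------------


def save_params(params: ModelParams, path) -> None:
    """Array archive + JSON architecture manifest."""
    import json

    arrays = {}
    for i, w in enumerate(params.gcn_weights):
        arrays[f"gcn_{i}"] = w
    for i, (w, b) in enumerate(zip(params.dense_W, params.dense_b)):
        arrays[f"dense_W_{i}"] = w
        arrays[f"dense_b_{i}"] = b
    manifest = {
        "n_nodes": params.arch.n_nodes,
        "feature_dim": params.arch.feature_dim,
        "gcn_dims": list(params.arch.gcn_dims),
        "dense_dims": list(params.arch.dense_dims),
        "n_classes": params.arch.n_classes,
        "activation": params.arch.activation,
        "readout": params.arch.readout,
        "seed": params.seed,
    }
    arrays["manifest"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_params(path) -> ModelParams:
    import json

    with np.load(path) as npz:
        manifest = json.loads(bytes(npz["manifest"].tobytes()).decode())
        arch = ArchConfig(
            n_nodes=manifest["n_nodes"], feature_dim=manifest["feature_dim"],
            gcn_dims=tuple(manifest["gcn_dims"]),
            dense_dims=tuple(manifest["dense_dims"]),
            n_classes=manifest["n_classes"], activation=manifest["activation"],
            readout=manifest["readout"],
        )
        n_gcn = len(arch.gcn_dims)
        n_dense = len(arch.dense_dims) + 1
        return ModelParams(
            gcn_weights=[npz[f"gcn_{i}"] for i in range(n_gcn)],
            dense_W=[npz[f"dense_W_{i}"] for i in range(n_dense)],
            dense_b=[npz[f"dense_b_{i}"] for i in range(n_dense)],
            arch=arch, seed=manifest["seed"],
        )
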