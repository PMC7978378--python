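"""The two deep classifiers behind the screening funnel's first stage.

* A dense feed-forward network ("DNN") over binary ECFP4 fingerprint bits:
  ReLU hidden layers with dropout and L2 weight decay, two-class softmax
  output, trained with Adam.
* A neural-graph-fingerprint network ("NFP", the paper field's "CNN" on
  molecular graphs): at each radius every atom's hidden vector is updated
  from the sum of itself and its neighbors through a learned linear map and
  ReLU, and a per-radius softmax projection writes each atom's contribution
  into a real-valued fingerprint, summed over atoms and radii. The
  fingerprint feeds a small dense softmax head.

Both are built on a compact reverse-mode automatic-differentiation engine
(`Tensor`) implemented here on numpy: a handful of vectorized ops with
closed-form VJPs and topological-sort backprop. Gradients are verified
against central finite differences in the test suite.

All randomness (initialization, epoch shuffling, dropout masks) derives from
the config seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .fingerprints import ATOM_FEATURE_DIM, MolGraph
from .screenmetrics import (ConfusionCounts, MetricSet, RankedList,
                            confusion_metrics, roc_auc)

__all__ = [
    "Tensor",
    "DNNConfig",
    "NFPConfig",
    "ModelParams",
    "train_dnn",
    "train_nfp",
    "predict_dnn",
    "predict_nfp",
    "nfp_forward",
    "dnn_loss",
    "nfp_loss",
    "dnn_loss_and_grads",
    "nfp_loss_and_grads",
    "grid_search_batch",
    "evaluate_predictions",
    "predict_filter",
    "intersect_filters",
    "save_params",
    "load_params",
]


# ---------------------------------------------------------------------------
# Reverse-mode autodiff
# ---------------------------------------------------------------------------

class Tensor:
    """A numpy array in a dynamically built computation graph.

    Only parameters are created with ``requires_grad=True``; constants
    (inputs, adjacency matrices, dropout masks) participate in the forward
    pass but receive no gradient.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_val = self.value @ other.value

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        return Tensor(out_val, parents=(self, other), backward=backward)

    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_val = self.value + other.value

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        return Tensor(out_val, parents=(self, other), backward=backward)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_val = self.value * other.value

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        return Tensor(out_val, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def relu(self) -> "Tensor":
        out_val = np.maximum(self.value, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.value > 0))

        return Tensor(out_val, parents=(self,), backward=backward)

    def row_softmax(self) -> "Tensor":
        z = self.value - self.value.max(axis=1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=1, keepdims=True)

        def backward(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=1, keepdims=True)))

        return Tensor(s, parents=(self,), backward=backward)

    def sumsq(self) -> "Tensor":
        out_val = np.sum(self.value ** 2)

        def backward(g):
            if self.requires_grad:
                self._accum(2.0 * g * self.value)

        return Tensor(out_val, parents=(self,), backward=backward)

    def softmax_xent(self, labels: np.ndarray) -> "Tensor":
        """Mean two-class cross-entropy of row logits against 0/1 labels."""
        z = self.value - self.value.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        n = self.value.shape[0]
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels.astype(int)] = 1.0
        loss = -np.sum(onehot * np.log(np.clip(p, 1e-300, None))) / n

        def backward(g):
            if self.requires_grad:
                self._accum(g * (p - onehot) / n)

        return Tensor(loss, parents=(self,), backward=backward)

    # -- backprop --------------------------------------------------------

    def _accum(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() must start from a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient back down to a broadcast operand's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# Configs and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DNNConfig:
    """Dense-network hyperparameters; defaults are the selected optimum
    (batch 250, lr 1e-3, 500 epochs, dropout 0.2, L2 1e-4, widths
    3000/2000/1000)."""

    batch_size: int = 250
    learning_rate: float = 0.001
    num_epochs: int = 500
    dropout: float = 0.2
    l2: float = 0.0001
    hidden_widths: tuple = (3000, 2000, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")


@dataclass(frozen=True)
class NFPConfig:
    """Graph-network hyperparameters; the selected optimum uses 5
    convolutional radii and batch size 200."""

    conv_layers: int = 5
    fp_length: int = 2048
    hidden_width: int = 100
    batch_size: int = 200
    learning_rate: float = 0.001
    num_epochs: int = 500
    l2: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_layers < 0:
            raise ValueError("conv_layers must be >= 0")


@dataclass
class ModelParams:
    """Learned weights plus the config that shaped them."""

    kind: str  # "dnn" | "nfp"
    config: object
    arrays: dict  # name -> ndarray

    def as_tensors(self) -> dict:
        return {k: Tensor(v.copy(), requires_grad=True)
                for k, v in self.arrays.items()}


def _init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-scale, scale, size=shape)


def _init_dnn(nbits: int, config: DNNConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    widths = [nbits, *config.hidden_widths, 2]
    arrays = {}
    for i, (din, dout) in enumerate(zip(widths[:-1], widths[1:])):
        arrays[f"W{i}"] = _init(rng, din, (din, dout))
        arrays[f"b{i}"] = np.zeros(dout)
    return arrays


def _init_nfp(config: NFPConfig, feat_dim: int = ATOM_FEATURE_DIM) -> dict:
    rng = np.random.default_rng(config.seed)
    H, F, L = config.hidden_width, config.fp_length, config.conv_layers
    arrays = {"Wo0": _init(rng, feat_dim, (feat_dim, F)), "bo0": np.zeros(F)}
    din = feat_dim
    for l in range(L):
        arrays[f"Wh{l}"] = _init(rng, din, (din, H))
        arrays[f"bh{l}"] = np.zeros(H)
        arrays[f"Wo{l + 1}"] = _init(rng, H, (H, F))
        arrays[f"bo{l + 1}"] = np.zeros(F)
        din = H
    arrays["Wd0"] = _init(rng, F, (F, H))
    arrays["bd0"] = np.zeros(H)
    arrays["Wd1"] = _init(rng, H, (H, 2))
    arrays["bd1"] = np.zeros(2)
    return arrays


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def _dnn_logits(X: np.ndarray, t: dict, config: DNNConfig,
                rng: Optional[np.random.Generator] = None) -> Tensor:
    """Hidden ReLU stack with inverted dropout (train mode iff rng given)."""
    h = Tensor(X)
    n_hidden = len(config.hidden_widths)
    for i in range(n_hidden):
        h = (h @ t[f"W{i}"] + t[f"b{i}"]).relu()
        if rng is not None and config.dropout > 0:
            keep = 1.0 - config.dropout
            mask = rng.random(h.value.shape) < keep
            h = h * Tensor(mask / keep)
    return h @ t[f"W{n_hidden}"] + t[f"b{n_hidden}"]


def _l2_penalty(t: dict, l2: float) -> Optional[Tensor]:
    if l2 == 0:
        return None
    total = None
    for name, p in t.items():
        if name.startswith(("W",)):  # biases are not decayed
            term = p.sumsq()
            total = term if total is None else total + term
    return Tensor(l2) * total


def _batch_graphs(graphs: Sequence[MolGraph]):
    """Stack molecule graphs block-diagonally: concatenated atom features,
    a block adjacency matrix, and a molecule-by-atom pooling indicator."""
    feats = np.concatenate([g.atom_features for g in graphs], axis=0)
    n_atoms = feats.shape[0]
    adj = np.zeros((n_atoms, n_atoms))
    pool = np.zeros((len(graphs), n_atoms))
    offset = 0
    for gi, g in enumerate(graphs):
        for i, nb in enumerate(g.neighbors):
            for j in nb:
                adj[offset + i, offset + j] = 1.0
        pool[gi, offset:offset + g.n_atoms] = 1.0
        offset += g.n_atoms
    return feats, adj, pool


def _nfp_fingerprint(graphs: Sequence[MolGraph], t: dict,
                     config: NFPConfig) -> Tensor:
    """Batched neural fingerprints: (n_molecules, fp_length)."""
    feats, adj, pool = _batch_graphs(graphs)
    A, P = Tensor(adj), Tensor(pool)
    h = Tensor(feats)
    fp = P @ (h @ t["Wo0"] + t["bo0"]).row_softmax()
    for l in range(config.conv_layers):
        msg = h + (A @ h)  # self + neighbor sum, permutation invariant
        h = (msg @ t[f"Wh{l}"] + t[f"bh{l}"]).relu()
        fp = fp + P @ (h @ t[f"Wo{l + 1}"] + t[f"bo{l + 1}"]).row_softmax()
    return fp


def _nfp_logits(graphs: Sequence[MolGraph], t: dict,
                config: NFPConfig) -> Tensor:
    fp = _nfp_fingerprint(graphs, t, config)
    h = (fp @ t["Wd0"] + t["bd0"]).relu()
    return h @ t["Wd1"] + t["bd1"]


def nfp_forward(graph: MolGraph, params: ModelParams) -> np.ndarray:
    """The learned fingerprint vector of a single molecule."""
    if params.kind != "nfp":
        raise ValueError("nfp_forward needs NFP parameters")
    t = {k: Tensor(v) for k, v in params.arrays.items()}
    return _nfp_fingerprint([graph], t, params.config).value[0]


# ---------------------------------------------------------------------------
# Losses (eval mode: no dropout) and gradients
# ---------------------------------------------------------------------------

def dnn_loss(X: np.ndarray, y: np.ndarray, params: ModelParams) -> float:
    t = {k: Tensor(v) for k, v in params.arrays.items()}
    loss = _dnn_logits(X, t, params.config).softmax_xent(y)
    pen = _l2_penalty(t, params.config.l2)
    return float((loss if pen is None else loss + pen).value)


def nfp_loss(graphs: Sequence[MolGraph], y: np.ndarray,
             params: ModelParams) -> float:
    t = {k: Tensor(v) for k, v in params.arrays.items()}
    loss = _nfp_logits(graphs, t, params.config).softmax_xent(y)
    pen = _l2_penalty(t, params.config.l2)
    return float((loss if pen is None else loss + pen).value)


def _loss_and_grads(build_loss, params: ModelParams):
    t = params.as_tensors()
    loss = build_loss(t)
    loss.backward()
    grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.value))
             for k, p in t.items()}
    return float(loss.value), grads


def dnn_loss_and_grads(X, y, params: ModelParams):
    """Analytic (loss, gradient dict) in eval mode, for verification."""

    def build(t):
        loss = _dnn_logits(X, t, params.config).softmax_xent(y)
        pen = _l2_penalty(t, params.config.l2)
        return loss if pen is None else loss + pen

    return _loss_and_grads(build, params)


def nfp_loss_and_grads(graphs, y, params: ModelParams):
    """Analytic (loss, gradient dict) for the graph network."""

    def build(t):
        loss = _nfp_logits(graphs, t, params.config).softmax_xent(y)
        pen = _l2_penalty(t, params.config.l2)
        return loss if pen is None else loss + pen

    return _loss_and_grads(build, params)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def _train(forward: Callable, inputs, y: np.ndarray, config,
           arrays: dict, kind: str) -> tuple[ModelParams, list]:
    _check_two_classes(y)
    n = len(y)
    t = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
    opt = Adam(t, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    log = []
    for epoch in range(config.num_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = forward(idx, t, rng)
            pen = _l2_penalty(t, config.l2)
            total = loss if pen is None else loss + pen
            if not np.isfinite(total.value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            total.backward()
            opt.step()
            epoch_loss += float(total.value)
            n_batches += 1
        log.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)})
    params = ModelParams(kind=kind, config=config,
                         arrays={k: p.value for k, p in t.items()})
    return params, log


def train_dnn(X: np.ndarray, y: np.ndarray,
              config: DNNConfig = DNNConfig()) -> tuple[ModelParams, list]:
    """Train the dense fingerprint classifier; reproducible under the seed."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    arrays = _init_dnn(X.shape[1], config)

    def forward(idx, t, rng):
        return _dnn_logits(X[idx], t, config, rng=rng).softmax_xent(y[idx])

    return _train(forward, X, y, config, arrays, "dnn")


def train_nfp(graphs: Sequence[MolGraph], y: np.ndarray,
              config: NFPConfig = NFPConfig()) -> tuple[ModelParams, list]:
    """Train the neural-graph-fingerprint classifier."""
    y = np.asarray(y)
    arrays = _init_nfp(config, feat_dim=graphs[0].atom_features.shape[1])

    def forward(idx, t, rng):
        batch = [graphs[i] for i in idx]
        return _nfp_logits(batch, t, config).softmax_xent(y[idx])

    return _train(forward, graphs, y, config, arrays, "nfp")


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_dnn(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Active-class probabilities for fingerprint rows."""
    if params.kind != "dnn":
        raise ValueError("predict_dnn needs DNN parameters")
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != params.arrays["W0"].shape[0]:
        raise ValueError("fingerprint length does not match the model")
    t = {k: Tensor(v) for k, v in params.arrays.items()}
    logits = _dnn_logits(X, t, params.config)
    return _softmax_rows(logits.value)[:, 1]


def predict_nfp(params: ModelParams,
                graphs: Sequence[MolGraph]) -> np.ndarray:
    """Active-class probabilities for molecule graphs."""
    if params.kind != "nfp":
        raise ValueError("predict_nfp needs NFP parameters")
    t = {k: Tensor(v) for k, v in params.arrays.items()}
    logits = _nfp_logits(graphs, t, params.config)
    return _softmax_rows(logits.value)[:, 1]


def evaluate_predictions(p_active: np.ndarray, y: np.ndarray,
                         threshold: float = 0.5) -> MetricSet:
    """SE/SP/Q+/Q-/MCC at the threshold, plus ROC AUC over the scores."""
    y = np.asarray(y).astype(bool)
    pred = np.asarray(p_active) > threshold
    cc = ConfusionCounts(
        tp=int(np.sum(pred & y)), fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)), fn=int(np.sum(~pred & y)))
    ms = confusion_metrics(cc)
    ranked = RankedList(entries=[(str(i), float(p), bool(t))
                                 for i, (p, t) in enumerate(zip(p_active, y))])
    return MetricSet(se=ms.se, sp=ms.sp, q_plus=ms.q_plus,
                     q_minus=ms.q_minus, mcc=ms.mcc, auc=roc_auc(ranked))


def grid_search_batch(train_inputs, train_y, test_inputs, test_y,
                      model_kind: str, batch_sizes: Sequence[int],
                      base_config=None) -> tuple[pd.DataFrame, ModelParams]:
    """Train one model per batch size; tabulate test metrics; pick the best.

    Returns (table, best_params) where the table has one row per batch size
    with SE, SP, Q+, Q-, MCC and AUC, and the best model maximizes MCC with
    AUC as the tie-break.
    """
    if not batch_sizes:
        raise ValueError("need at least one batch size")
    if model_kind == "dnn":
        base = base_config or DNNConfig()
        trainer, predictor = train_dnn, predict_dnn
    elif model_kind == "nfp":
        base = base_config or NFPConfig()
        trainer, predictor = train_nfp, predict_nfp
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    rows, fitted = [], []
    for bs in batch_sizes:
        config = replace(base, batch_size=int(bs))
        params, _ = trainer(train_inputs, np.asarray(train_y), config)
        p = predictor(params, test_inputs)
        ms = evaluate_predictions(p, test_y)
        rows.append({"batch_size": int(bs), "se": ms.se, "sp": ms.sp,
                     "q_plus": ms.q_plus, "q_minus": ms.q_minus,
                     "mcc": ms.mcc, "auc": ms.auc})
        fitted.append(params)
    table = pd.DataFrame(rows)
    best_idx = table.sort_values(["mcc", "auc"],
                                 ascending=False, kind="stable").index[0]
    return table, fitted[int(best_idx)]


def predict_filter(params: ModelParams, ids: Sequence[str], inputs,
                   threshold: float = 0.5) -> tuple[set, pd.DataFrame]:
    """Ids whose active-class probability exceeds the threshold.

    Returns (passing id set, scores table with id, p_active, pass_flag).
    """
    if params.kind == "dnn":
        p = predict_dnn(params, inputs)
    else:
        p = predict_nfp(params, inputs)
    passing = {i for i, pi in zip(ids, p) if pi > threshold}
    scores = pd.DataFrame({"id": list(ids), "p_active": p,
                           "pass_flag": [i in passing for i in ids]})
    return passing, scores


def intersect_filters(a: set, b: set) -> set:
    """Compounds retained by both classifiers (the dual-model gate)."""
    return set(a) & set(b)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    """Serialize weights and config to an .npz checkpoint."""
    meta = {"kind": params.kind,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in params.config.__dict__.items()}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **params.arrays)


def load_params(path) -> ModelParams:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = meta["config"]
    if meta["kind"] == "dnn":
        cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        config = DNNConfig(**cfg_dict)
    else:
        config = NFPConfig(**cfg_dict)
    arrays = {k: data[k] for k in data.files if k != "__meta__"}
    return ModelParams(kind=meta["kind"], config=config, arrays=arrays)
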