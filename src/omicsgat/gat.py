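"""Graph attention network for patient similarity graphs.

A two-layer GAT trained as a transductive node classifier on subtype labels.
For node i with neighborhood N_i (graph neighbors plus a self-loop):

    c_ij   = LeakyReLU( a^T [W x_i || W x_j] )          raw attention score
    alpha_ij = exp(c_ij) / sum_{k in N_i} exp(c_ik)     softmax normalization
    h_i    = sigma( sum_{j in N_i} alpha_ij W x_j )     neighbor aggregation

Layer 1 runs H attention heads whose outputs are concatenated (total width =
hidden_dim) and passed through ELU; layer 2 maps to class scores with no
nonlinearity before the softmax cross-entropy.  Forward and reverse passes
are plain numpy; gradients are hand-derived and checked against finite
differences in the test suite.  Optimization is full-batch Adam.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score

from .io import OmicsValidationError, logger
from .similarity import PatientGraph


@dataclass
class GATLayerParams:
    """One attention head: shared linear map W (p × m) and attention vector
    a (2p), split internally as a = [a_dst || a_src]."""

    W: np.ndarray
    a: np.ndarray
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float).ravel()
        p = self.W.shape[0]
        if self.a.shape[0] != 2 * p:
            raise OmicsValidationError(
                f"attention vector must have length 2p={2 * p}, got {self.a.shape[0]}")


@dataclass
class AttentionState:
    """Per-directed-edge attention quantities; edge (i, j) means neighbor j
    contributes to node i.  Edges are grouped by i (ascending), so softmax
    normalization is a contiguous segment reduction."""

    edge_index: np.ndarray                  # (E, 2) int: columns (i, j)
    c: np.ndarray                           # raw scores, (E,)
    alpha: np.ndarray | None = None         # normalized coefficients, (E,)
    _offsets: np.ndarray | None = field(default=None, repr=False)

    def offsets(self) -> np.ndarray:
        if self._offsets is None:
            dst = self.edge_index[:, 0]
            self._offsets = np.searchsorted(dst, np.arange(dst.max() + 1))
        return self._offsets


@dataclass
class EmbeddingMatrix:
    """Per-node hidden representations h_i from one trained GAT."""

    values: np.ndarray
    sample_ids: list[str]
    omics_code: str | None = None
    layer: str = "hidden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise OmicsValidationError("embedding contains non-finite values")
        if self.values.shape[0] != len(self.sample_ids):
            raise OmicsValidationError("one embedding row per sample required")


# ---------------------------------------------------------------------------
# functional building blocks (single head)

def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def attention_scores(params: GATLayerParams, features: np.ndarray,
                     graph: PatientGraph) -> AttentionState:
    """Raw scores c_ij = LeakyReLU(a^T [W x_i || W x_j]) for every directed
    neighbor pair (self-loops included)."""
    x = np.asarray(features, dtype=float)
    p, m = params.W.shape
    if x.shape[1] != m:
        raise OmicsValidationError(
            f"feature dimension mismatch: W expects m={m}, features have {x.shape[1]}")
    if x.shape[0] != graph.n_nodes:
        raise OmicsValidationError("one feature row per graph node required")
    edge_index = graph.edge_index()
    z = x @ params.W.T
    a_dst, a_src = params.a[:p], params.a[p:]
    s = z[edge_index[:, 0]] @ a_dst + z[edge_index[:, 1]] @ a_src
    return AttentionState(edge_index, _leaky_relu(s, params.leaky_slope))


def normalize_attention(state: AttentionState) -> AttentionState:
    """Softmax of c over each node's neighborhood (max-subtracted)."""
    dst = state.edge_index[:, 0]
    off = state.offsets()
    assert off.size and np.diff(np.r_[off, len(dst)]).min() >= 1, \
        "every node must have a nonempty neighborhood (self-loop guaranteed)"
    cmax = np.maximum.reduceat(state.c, off)
    ex = np.exp(state.c - cmax[dst])
    denom = np.add.reduceat(ex, off)
    state.alpha = ex / denom[dst]
    return state


def aggregate_neighbors(state: AttentionState, params: GATLayerParams,
                        features: np.ndarray, activation: str = "elu",
                        sample_ids: list[str] | None = None) -> EmbeddingMatrix:
    """h_i = sigma( sum_{j in N_i} alpha_ij W x_j ).

    The neighbor features (W x_j), not the center's own (W x_i), enter the
    sum — with the self-loop the center still contributes its own term.
    """
    if state.alpha is None:
        raise OmicsValidationError("normalize_attention must run before aggregation")
    x = np.asarray(features, dtype=float)
    z = x @ params.W.T
    src = state.edge_index[:, 1]
    msg = state.alpha[:, None] * z[src]
    agg = np.add.reduceat(msg, state.offsets(), axis=0)
    out = _elu(agg) if activation == "elu" else agg
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(out))]
    return EmbeddingMatrix(out, ids)


# ---------------------------------------------------------------------------
# vectorized layer with backward pass

class _HeadCache:
    __slots__ = ("z", "s", "alpha", "agg", "out")


def _head_forward(x, W, a, edge_index, offsets, slope, activation):
    cache = _HeadCache()
    p = W.shape[0]
    dst, src = edge_index[:, 0], edge_index[:, 1]
    cache.z = x @ W.T
    s_lin = cache.z[dst] @ a[:p] + cache.z[src] @ a[p:]
    cache.s = s_lin
    c = _leaky_relu(s_lin, slope)
    cmax = np.maximum.reduceat(c, offsets)
    ex = np.exp(c - cmax[dst])
    denom = np.add.reduceat(ex, offsets)
    cache.alpha = ex / denom[dst]
    cache.agg = np.add.reduceat(cache.alpha[:, None] * cache.z[src], offsets, axis=0)
    cache.out = _elu(cache.agg) if activation == "elu" else cache.agg
    return cache


def _head_backward(dout, x, W, a, edge_index, offsets, slope, activation, cache):
    p = W.shape[0]
    n = x.shape[0]
    dst, src = edge_index[:, 0], edge_index[:, 1]
    if activation == "elu":
        dagg = dout * np.where(cache.agg > 0, 1.0, np.exp(np.minimum(cache.agg, 0.0)))
    else:
        dagg = dout
    # aggregation: agg_i = sum_e alpha_e z[src_e]
    dalpha = np.einsum("ep,ep->e", dagg[dst], cache.z[src])
    dz = np.zeros_like(cache.z)
    np.add.at(dz, src, cache.alpha[:, None] * dagg[dst])
    # softmax backward (per destination segment)
    gsum = np.add.reduceat(cache.alpha * dalpha, offsets)
    dc = cache.alpha * (dalpha - gsum[dst])
    ds = dc * np.where(cache.s > 0, 1.0, slope)
    # s = z[dst]@a1 + z[src]@a2
    dpi = np.bincount(dst, weights=ds, minlength=n)
    dpj = np.bincount(src, weights=ds, minlength=n)
    da = np.concatenate([cache.z.T @ dpi, cache.z.T @ dpj])
    dz += dpi[:, None] * a[:p] + dpj[:, None] * a[p:]
    dW = dz.T @ x
    dx = dz @ W
    return dx, dW, da


class _TwoLayerGAT:
    """Parameters and forward/backward for the fixed two-layer architecture."""

    def __init__(self, m: int, hidden_dim: int, n_classes: int, heads: int,
                 leaky_slope: float, rng: np.random.Generator):
        if hidden_dim % heads != 0:
            raise OmicsValidationError(
                f"heads={heads} must divide hidden_dim={hidden_dim}")
        self.heads = heads
        self.p1 = hidden_dim // heads
        self.hidden_dim = hidden_dim
        self.n_classes = n_classes
        self.slope = leaky_slope

        def glorot(shape):
            lim = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-lim, lim, size=shape)

        self.W1 = [glorot((self.p1, m)) for _ in range(heads)]
        self.a1 = [glorot((2 * self.p1,)) for _ in range(heads)]
        self.W2 = glorot((n_classes, hidden_dim))
        self.a2 = glorot((2 * n_classes,))

    def parameters(self):
        return [*self.W1, *self.a1, self.W2, self.a2]

    def set_parameters(self, params):
        h = self.heads
        self.W1 = [np.array(p) for p in params[:h]]
        self.a1 = [np.array(p) for p in params[h:2 * h]]
        self.W2 = np.array(params[2 * h])
        self.a2 = np.array(params[2 * h + 1])

    def forward(self, x, edge_index, offsets):
        self._c1 = [_head_forward(x, W, a, edge_index, offsets, self.slope, "elu")
                    for W, a in zip(self.W1, self.a1)]
        h1 = np.concatenate([c.out for c in self._c1], axis=1)
        self._h1 = h1
        self._c2 = _head_forward(h1, self.W2, self.a2, edge_index, offsets,
                                 self.slope, "identity")
        return self._c2.out, h1

    def backward(self, dlogits, x, edge_index, offsets):
        dh1, dW2, da2 = _head_backward(dlogits, self._h1, self.W2, self.a2,
                                       edge_index, offsets, self.slope,
                                       "identity", self._c2)
        grads_W1, grads_a1 = [], []
        for h, (W, a, cache) in enumerate(zip(self.W1, self.a1, self._c1)):
            blk = dh1[:, h * self.p1:(h + 1) * self.p1]
            _, dW, da = _head_backward(blk, x, W, a, edge_index, offsets,
                                       self.slope, "elu", cache)
            grads_W1.append(dW)
            grads_a1.append(da)
        return [*grads_W1, *grads_a1, dW2, da2]


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class GATClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer graph attention node classifier (scikit-learn style).

    Parameters
    ----------
    hidden_dim : total width of the concatenated layer-1 heads (default 512).
    learning_rate, epochs : full-batch Adam settings (defaults 0.001, 200).
    heads : number of layer-1 attention heads; must divide ``hidden_dim``.
    leaky_slope : LeakyReLU negative slope in the attention scores (0.2).
    random_state : seed for parameter initialization.

    Fitted attributes: ``classes_``, ``embedding_`` (layer-1 hidden
    representation for every node, n × hidden_dim), ``history_`` (per-epoch
    train loss and validation macro-F1), ``best_epoch_``.
    """

    def __init__(self, hidden_dim: int = 512, learning_rate: float = 0.001,
                 epochs: int = 200, heads: int = 1, leaky_slope: float = 0.2,
                 random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.heads = heads
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    def fit(self, X, y, graph: PatientGraph = None, train_idx=None, val_idx=None):
        if graph is None:
            raise OmicsValidationError("GATClassifier.fit requires graph=")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        n = X.shape[0]
        train_idx = np.arange(n) if train_idx is None else np.asarray(train_idx)
        present = set(y_codes[train_idx].tolist())
        missing = [str(self.classes_[k]) for k in range(len(self.classes_))
                   if k not in present]
        if missing:
            raise OmicsValidationError(
                f"training split is missing classes {missing} (stratification violated)")
        rng = np.random.default_rng(self.random_state)
        model = _TwoLayerGAT(X.shape[1], self.hidden_dim, len(self.classes_),
                             self.heads, self.leaky_slope, rng)
        edge_index = graph.edge_index()
        offsets = np.searchsorted(edge_index[:, 0], np.arange(n))
        onehot = np.eye(len(self.classes_))[y_codes]
        opt = _Adam(model.parameters(), self.learning_rate)
        best = (-np.inf, None, -1)
        history = {"loss": [], "val_macro_f1": []}
        for epoch in range(self.epochs):
            logits, _ = model.forward(X, edge_index, offsets)
            prob = _softmax_rows(logits)
            tr = train_idx
            loss = -np.mean(np.log(prob[tr, y_codes[tr]] + 1e-12))
            history["loss"].append(float(loss))
            dlogits = np.zeros_like(prob)
            dlogits[tr] = (prob[tr] - onehot[tr]) / len(tr)
            grads = model.backward(dlogits, X, edge_index, offsets)
            opt.step(model.parameters(), grads)
            if val_idx is not None and len(val_idx) > 0:
                pred = logits[val_idx].argmax(axis=1)
                score = f1_score(y_codes[val_idx], pred, average="macro",
                                 zero_division=0)
            else:
                score = -loss
            history["val_macro_f1"].append(float(score) if val_idx is not None else np.nan)
            if score > best[0]:
                best = (score, [np.array(p) for p in model.parameters()], epoch)
        if best[1] is not None:
            model.set_parameters(best[1])
        logits, h1 = model.forward(X, edge_index, offsets)
        self.model_ = model
        self.graph_ = graph
        self._edge_index = edge_index
        self._offsets = offsets
        self.logits_ = logits
        self.embedding_ = h1
        self.history_ = history
        self.best_epoch_ = best[2]
        return self

    def decision_function(self, X=None):
        if X is None:
            return self.logits_
        X = np.asarray(X, dtype=float)
        logits, _ = self.model_.forward(X, self._edge_index, self._offsets)
        return logits

    def predict_proba(self, X=None):
        return _softmax_rows(self.decision_function(X))

    def predict(self, X=None):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def transform(self, X=None):
        """Layer-1 hidden embedding for every node."""
        if X is None:
            return self.embedding_
        X = np.asarray(X, dtype=float)
        _, h1 = self.model_.forward(X, self._edge_index, self._offsets)
        return h1


def gat_forward(clf_or_model, features, graph: PatientGraph):
    """Forward pass returning (class scores, hidden embedding) for all nodes."""
    x = np.asarray(features, dtype=float)
    edge_index = graph.edge_index()
    offsets = np.searchsorted(edge_index[:, 0], np.arange(graph.n_nodes))
    model = clf_or_model.model_ if isinstance(clf_or_model, GATClassifier) else clf_or_model
    return model.forward(x, edge_index, offsets)


def train_gat(features, graph: PatientGraph, labels, train_idx, val_idx,
              grid: dict | None = None, sample_ids=None, omics_code=None,
              random_state: int = 0, **config):
    """Train one per-omics GAT, optionally grid-searching hyperparameters.

    ``grid`` maps GATClassifier parameter names to candidate lists; the
    configuration with the best validation macro-F1 wins.  Without a grid a
    single configuration (defaults overridden by ``config``) is trained.
    Returns ``(fitted GATClassifier, EmbeddingMatrix)``.
    """
    y = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    candidates: list[dict]
    if grid:
        keys = sorted(grid)
        candidates = [dict(zip(keys, vals))
                      for vals in itertools.product(*(grid[k] for k in keys))]
    else:
        candidates = [{}]
    best_clf, best_score = None, -np.inf
    for cand in candidates:
        params = {"hidden_dim": 512, "learning_rate": 0.001, "epochs": 200,
                  "heads": 1, "random_state": random_state, **config, **cand}
        clf = GATClassifier(**params)
        clf.fit(features, y, graph=graph, train_idx=train_idx, val_idx=val_idx)
        pred = clf.predict()[val_idx]
        score = f1_score(y[val_idx], pred, average="macro", zero_division=0)
        if score > best_score:
            best_clf, best_score = clf, score
        if len(candidates) > 1:
            logger.info("gat: config %s -> val macro-F1 %.3f", cand or "default", score)
    ids = sample_ids if sample_ids is not None else (
        labels.sample_ids if hasattr(labels, "sample_ids") else
        [str(i) for i in range(len(y))])
    emb = EmbeddingMatrix(best_clf.embedding_, list(ids), omics_code)
    return best_clf, emb
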