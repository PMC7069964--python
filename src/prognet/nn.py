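"""Minimal deterministic feed-forward networks in numpy.

Two architectures: a plain ReLU chain with a logistic output unit, and a
bimodal network whose two ReLU branches (expression, clinical) are
concatenated at their last hidden layers and followed by further ReLU
layers and a logistic head. Training uses minibatch Nadam on binary
cross-entropy with an L2 penalty on all weight matrices, early stopping
on validation loss, and best-epoch weight restoration. Everything is
seeded and single-threaded-deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeedForward", "BimodalNet", "Nadam", "TrainHistory",
           "train_network"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_chain(rng, input_dim, widths):
    layers = []
    fan = input_dim
    for w in widths:
        if w <= 0:
            raise ValueError("hidden width must be positive")
        layers.append([_glorot(rng, fan, w), np.zeros(w)])
        fan = w
    return layers


def _chain_forward(layers, X, keep=False):
    acts = [X]
    h = X
    for W, b in layers:
        h = _relu(h @ W + b)
        if keep:
            acts.append(h)
    return (h, acts) if keep else h


def _bce(p, y):
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class FeedForward:
    """ReLU chain + logistic scalar head (one branch or a unimodal model)."""

    def __init__(self, input_dim: int, hidden_widths, seed: int = 0,
                 l2: float = 1e-4):
        if input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if not hidden_widths:
            raise ValueError("hidden_widths must be nonempty")
        rng = np.random.default_rng(seed)
        self.input_dim = int(input_dim)
        self.hidden_widths = tuple(int(w) for w in hidden_widths)
        self.l2 = float(l2)
        self.hidden = _init_chain(rng, input_dim, self.hidden_widths)
        self.head = [_glorot(rng, self.hidden_widths[-1], 1), np.zeros(1)]

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        out = []
        for W, b in self.hidden:
            out += [W, b]
        out += self.head
        return out

    def set_params(self, values):
        for p, v in zip(self.params, values):
            p[...] = v

    def copy_params(self):
        return [p.copy() for p in self.params]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / loss / gradients -----------------------------------------
    def branch_activation(self, X):
        """Last hidden-layer activation (the representation merged in the
        bimodal network)."""
        return _chain_forward(self.hidden, np.asarray(X, float))

    def predict_proba(self, X):
        h = self.branch_activation(X)
        W, b = self.head
        return _sigmoid(h @ W + b).ravel()

    def _penalty(self):
        return self.l2 * sum(float((W**2).sum()) for W, _ in self.hidden + [self.head])

    def loss(self, X, y):
        return _bce(self.predict_proba(X), np.asarray(y, float)) + self._penalty()

    def grads(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n = X.shape[0]
        h, acts = _chain_forward(self.hidden, X, keep=True)
        W, b = self.head
        p = _sigmoid(h @ W + b).ravel()
        loss = _bce(p, y) + self._penalty()
        dz = ((p - y) / n)[:, None]
        gW_head = h.T @ dz + 2.0 * self.l2 * W
        gb_head = dz.sum(axis=0)
        dh = dz @ W.T
        grads = []
        for i in range(len(self.hidden) - 1, -1, -1):
            Wi, _ = self.hidden[i]
            dzh = dh * (acts[i + 1] > 0)
            grads.append(dzh.sum(axis=0))
            grads.append(acts[i].T @ dzh + 2.0 * self.l2 * Wi)
            dh = dzh @ Wi.T
        grads.reverse()
        grads += [gW_head, gb_head]
        return loss, grads


class BimodalNet:
    """Two ReLU branches concatenated, post-merge ReLU layers, logistic head.

    Branch weights may be seeded from pre-trained unimodal models; the
    post-merge stack and head are freshly initialized.
    """

    def __init__(self, micro_dim: int, micro_widths, clin_dim: int,
                 clin_widths, post_widths, seed: int = 0, l2: float = 1e-4):
        rng = np.random.default_rng(seed)
        self.l2 = float(l2)
        self.micro_dim, self.clin_dim = int(micro_dim), int(clin_dim)
        self.micro = _init_chain(rng, micro_dim, micro_widths)
        self.clin = _init_chain(rng, clin_dim, clin_widths)
        self.merged_width = int(micro_widths[-1] + clin_widths[-1])
        self.post = _init_chain(rng, self.merged_width, post_widths)
        last = post_widths[-1] if post_widths else self.merged_width
        self.head = [_glorot(rng, last, 1), np.zeros(1)]

    def load_branches(self, micro_model: FeedForward, clin_model: FeedForward):
        """Initialize branch weights from trained unimodal models (their
        logistic heads are discarded)."""
        for tgt, src, dim in ((self.micro, micro_model, self.micro_dim),
                              (self.clin, clin_model, self.clin_dim)):
            if src.input_dim != dim or len(src.hidden) != len(tgt):
                raise ValueError("unimodal model incompatible with branch spec")
            for (Wt, bt), (Ws, bs) in zip(tgt, src.hidden):
                if Wt.shape != Ws.shape:
                    raise ValueError("branch layer shape mismatch")
                Wt[...] = Ws
                bt[...] = bs
        return self

    @property
    def params(self):
        out = []
        for chain in (self.micro, self.clin, self.post):
            for W, b in chain:
                out += [W, b]
        out += self.head
        return out

    def set_params(self, values):
        for p, v in zip(self.params, values):
            p[...] = v

    def copy_params(self):
        return [p.copy() for p in self.params]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def _split(self, X):
        Xm, Xc = X
        Xm = np.asarray(Xm, float)
        Xc = np.asarray(Xc, float)
        if Xm.shape[1] != self.micro_dim or Xc.shape[1] != self.clin_dim:
            raise ValueError("input dimensions do not match the branches")
        return Xm, Xc

    def predict_proba(self, X):
        Xm, Xc = self._split(X)
        h = np.concatenate([_chain_forward(self.micro, Xm),
                            _chain_forward(self.clin, Xc)], axis=1)
        h = _chain_forward(self.post, h)
        W, b = self.head
        return _sigmoid(h @ W + b).ravel()

    def _penalty(self):
        mats = [W for chain in (self.micro, self.clin, self.post)
                for W, _ in chain] + [self.head[0]]
        return self.l2 * sum(float((W**2).sum()) for W in mats)

    def loss(self, X, y):
        return _bce(self.predict_proba(X), np.asarray(y, float)) + self._penalty()

    def grads(self, X, y):
        Xm, Xc = self._split(X)
        y = np.asarray(y, float)
        n = Xm.shape[0]
        hm, acts_m = _chain_forward(self.micro, Xm, keep=True)
        hc, acts_c = _chain_forward(self.clin, Xc, keep=True)
        h0 = np.concatenate([hm, hc], axis=1)
        hp, acts_p = _chain_forward(self.post, h0, keep=True)
        W, b = self.head
        p = _sigmoid(hp @ W + b).ravel()
        loss = _bce(p, y) + self._penalty()
        dz = ((p - y) / n)[:, None]
        gW_head = hp.T @ dz + 2.0 * self.l2 * W
        gb_head = dz.sum(axis=0)
        dh = dz @ W.T

        def chain_back(chain, acts, dh):
            gs = []
            for i in range(len(chain) - 1, -1, -1):
                Wi, _ = chain[i]
                dzh = dh * (acts[i + 1] > 0)
                gs.append(dzh.sum(axis=0))
                gs.append(acts[i].T @ dzh + 2.0 * self.l2 * Wi)
                dh = dzh @ Wi.T
            gs.reverse()
            return gs, dh

        g_post, dh0 = chain_back(self.post, acts_p, dh)
        wm = self.micro[-1][0].shape[1]
        g_micro, _ = chain_back(self.micro, acts_m, dh0[:, :wm])
        g_clin, _ = chain_back(self.clin, acts_c, dh0[:, wm:])
        return loss, g_micro + g_clin + g_post + [gW_head, gb_head]


class Nadam:
    """Nesterov-momentum Adam (Dozat 2016) with bias correction."""

    def __init__(self, lr: float = 0.006, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = None
        self._v = None

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1**(t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _take(X, idx):
    if isinstance(X, tuple):
        return tuple(x[idx] for x in X)
    return X[idx]


def _n_rows(X):
    return X[0].shape[0] if isinstance(X, tuple) else X.shape[0]


def train_network(net, X, y, X_val, y_val, *, learning_rate: float = 0.006,
                  max_epochs: int = 100, batch_size: int = 20,
                  patience: int = 30, seed: int = 0) -> TrainHistory:
    """Minibatch Nadam training with early stopping on validation loss.

    Stops once the validation loss has not improved for more than
    ``patience`` epochs; the network is restored to the weights of the
    epoch with minimum validation loss. Deterministic for a fixed seed.
    """
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    opt = Nadam(lr=learning_rate)
    hist = TrainHistory()
    n = _n_rows(X)
    best_loss = np.inf
    best_params = net.copy_params()
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            _, grads = net.grads(_take(X, idx), y[idx])
            opt.step(net.params, grads)
        hist.train_loss.append(net.loss(X, y))
        vl = net.loss(X_val, y_val)
        hist.val_loss.append(vl)
        if vl < best_loss:
            best_loss = vl
            best_params = net.copy_params()
            hist.best_epoch = epoch
        if epoch - hist.best_epoch > patience:
            break
    net.set_params(best_params)
    return hist
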