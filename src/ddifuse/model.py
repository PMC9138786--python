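"""Attention fusion model: channel reducers, attention, classifier head.

Per drug, the three channels are reduced to 64 dimensions each — the
chemical-sequence matrix by a single 2-D convolution layer (64 kernels)
with global average pooling, the network embedding by a 64-unit dense
layer, and the N-dimensional fused-similarity row by dense layers of 300
and 64 units.  The three 64-vectors form a 3-token sequence fused by
scaled dot-product attention,

    theta~ = softmax(Q K^T / sqrt(d_k)) V,  d_k = 64,

with learned 64x64 projections.  A pair of drugs is represented by the
concatenation of the two fused 192-vectors; the classifier head has three
hidden dense layers with dropout and a sigmoid output, trained end-to-end
with binary cross-entropy and Adam.  Training includes both orderings of
every pair and prediction averages score(a,b) and score(b,a), so reported
scores are symmetric by construction.

Everything is plain NumPy (float64) and bit-reproducible per seed in
single-threaded mode; the CBOW table, graph embedding and fused similarity
are precomputed inputs held fixed during training.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

CHANNELS = ("chem", "net", "bio")


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


def _softmax_last(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def im2col(mats: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Unfold (n, H, W) one-channel images into (n, H*W, kernel**2)
    patch matrices with zero padding preserving the spatial size."""
    if mats.ndim == 2:
        mats = mats[None]
    n, H, W = mats.shape
    p = kernel // 2
    padded = np.pad(mats, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(padded, (kernel, kernel), axis=(1, 2))
    return np.ascontiguousarray(win.reshape(n, H * W, kernel * kernel))


class ConvReducer:
    """One 2-D convolution layer + global average pooling.

    Treats the L_max x d drug matrix as a one-channel image; ``n_kernels``
    square kernels with bias, a ReLU (or linear) nonlinearity, and a
    global average pool over both spatial axes yield one value per kernel.
    """

    def __init__(self, n_kernels: int = 64, kernel_size: int = 3,
                 activation: str = "relu", seed: int = 0,
                 weights: np.ndarray | None = None,
                 bias: np.ndarray | None = None):
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        k2 = kernel_size * kernel_size
        rng = np.random.default_rng(seed)
        self.W = (weights.reshape(k2, n_kernels) if weights is not None
                  else rng.standard_normal((k2, n_kernels))
                  * math.sqrt(2.0 / k2))
        self.b = bias if bias is not None else np.zeros(n_kernels)

    def reduce(self, matrix: np.ndarray) -> np.ndarray:
        """Pool a single (H, W) matrix to an ``n_kernels``-vector."""
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape "
                             f"{matrix.shape}")
        cols = im2col(matrix[None], self.kernel_size)
        pre = cols[0] @ self.W + self.b
        if self.activation == "relu":
            pre = _relu(pre)
        return pre.mean(axis=0)


def cnn_reduce(matrix: np.ndarray,
               reducer: ConvReducer | None = None) -> np.ndarray:
    """Reduce a drug-sequence matrix to one value per convolution kernel."""
    if reducer is None:
        reducer = ConvReducer()
    return reducer.reduce(matrix)


@dataclass
class DrugFeatureBundle:
    """The three 64-dim channel vectors of one drug (zeros when missing)."""

    chem: np.ndarray
    net: np.ndarray
    bio: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.chem, self.net, self.bio])


@dataclass
class AttentionBlock:
    """Scaled dot-product attention projections over 64-dim tokens."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    d_k: int = 64

    @classmethod
    def random(cls, dim: int = 64, seed: int = 0) -> "AttentionBlock":
        rng = np.random.default_rng(seed)
        s = 1.0 / math.sqrt(dim)
        return cls(W_Q=rng.standard_normal((dim, dim)) * s,
                   W_K=rng.standard_normal((dim, dim)) * s,
                   W_V=rng.standard_normal((dim, dim)) * s, d_k=dim)


def attention_weights(tokens: np.ndarray,
                      block: AttentionBlock) -> np.ndarray:
    """The (T, T) softmax attention matrix for a token stack; rows sum
    to one."""
    X = np.asarray(tokens, dtype=np.float64)
    Q = X @ block.W_Q
    K = X @ block.W_K
    return _softmax_last(Q @ K.T / math.sqrt(block.d_k))


def attention_fuse(bundle, block: AttentionBlock) -> np.ndarray:
    """Fuse a drug's channel tokens into one concatenated vector.

    The tokens (rows of the stacked bundle) are enhanced by
    ``softmax(QK^T/sqrt(d_k)) V`` and concatenated; for three 64-dim
    channels the result is a 192-vector.
    """
    X = bundle.stack() if isinstance(bundle, DrugFeatureBundle) \
        else np.asarray(bundle, dtype=np.float64)
    A = attention_weights(X, block)
    V = X @ block.W_V
    return (A @ V).reshape(-1)


def pair_representation(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Concatenate the two drugs' fused vectors into a pair vector."""
    return np.concatenate([np.asarray(fa).ravel(), np.asarray(fb).ravel()])


@dataclass
class DrugFeatures:
    """Frozen per-drug channel inputs over the canonical drug ordering.

    ``chem`` holds the L_max x d sequence matrices, ``net`` the graph
    embedding vectors (zeros for drugs under the isolated-node fallback),
    ``bio`` the fused-similarity rows.
    """

    drugs: list[str]
    chem: np.ndarray  # (n, L, d)
    net: np.ndarray   # (n, d_net)
    bio: np.ndarray   # (n, N)
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {d: i for i, d in enumerate(self.drugs)}

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def missing_mask(self) -> np.ndarray:
        """True for drugs whose every channel is all-zero."""
        return ((np.abs(self.chem).sum(axis=(1, 2)) == 0)
                & (np.abs(self.net).sum(axis=1) == 0)
                & (np.abs(self.bio).sum(axis=1) == 0))


class DDIClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end attention-fusion classifier over precomputed channels.

    Parameters
    ----------
    features : DrugFeatures
        Frozen channel inputs; ``fit``'s ``X`` is an (n, 2) integer array
        of drug indices into ``features``.
    hidden : tuple, default (256, 128, 64)
        Classifier-head hidden sizes (three layers).
    dropout : float, default 0.3
        Dropout rate on the head's hidden layers during training.
    lr : float, default 1e-3
        Adam initial learning rate.
    epochs, batch_size, patience, val_fraction :
        Optimisation budget; early stopping monitors validation BCE and
        restores the best weights.
    use_attention : bool, default True
        If False the three channel tokens are plainly concatenated.
    channels : tuple, default ("chem", "net", "bio")
        Ablation switch; a channel not listed contributes a zero token.
    token_dim : int, default 64
        Channel token width (= CNN kernels = dense reducer units).
    bio_hidden : int, default 300
        First dense layer of the biological-function reducer.
    seed : int, default 0

    Attributes
    ----------
    params_ : dict of weight arrays after fitting.
    history_ : per-epoch train/validation loss.
    classes_ : array([0, 1]).
    """

    def __init__(self, features=None, hidden=(256, 128, 64), dropout=0.3,
                 lr=1e-3, epochs=40, batch_size=1024, patience=8,
                 val_fraction=0.1, use_attention=True,
                 channels=CHANNELS, token_dim=64, bio_hidden=300,
                 conv_kernel=3, conv_chunk=8, seed=0):
        self.features = features
        self.hidden = hidden
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.use_attention = use_attention
        self.channels = channels
        self.token_dim = token_dim
        self.bio_hidden = bio_hidden
        self.conv_kernel = conv_kernel
        self.conv_chunk = conv_chunk
        self.seed = seed

    # ---------------- parameter handling ----------------

    def _init_params(self, rng) -> dict:
        d = self.token_dim
        k2 = self.conv_kernel ** 2
        nbio = self.features.bio.shape[1]
        dnet = self.features.net.shape[1]

        def he(fan_in, shape):
            return rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)

        p = {
            "conv_W": he(k2, (k2, d)), "conv_b": np.zeros(d),
            "net_W": he(dnet, (dnet, d)), "net_b": np.zeros(d),
            "bio_W1": he(nbio, (nbio, self.bio_hidden)),
            "bio_b1": np.zeros(self.bio_hidden),
            "bio_W2": he(self.bio_hidden, (self.bio_hidden, d)),
            "bio_b2": np.zeros(d),
        }
        if self.use_attention:
            s = 1.0 / math.sqrt(d)
            for name in ("attn_Q", "attn_K", "attn_V"):
                p[name] = rng.standard_normal((d, d)) * s
        sizes = [3 * d * 2] + list(self.hidden) + [1]
        for li in range(len(sizes) - 1):
            p[f"head_W{li}"] = he(sizes[li], (sizes[li], sizes[li + 1]))
            p[f"head_b{li}"] = np.zeros(sizes[li + 1])
        return p

    # ---------------- forward / backward ----------------

    def _encode_drugs(self, u: np.ndarray, p: dict, cache: dict | None):
        """Channel reducers + attention for the unique drugs ``u``.

        Returns the (U, 3*token_dim) fused representations; fills
        ``cache`` (when given) with what the backward pass needs.
        """
        d = self.token_dim
        U = len(u)
        feats = self.features
        toks = np.zeros((U, 3, d))

        if "chem" in self.channels:
            # float32 + cached ReLU masks keep the conv pass within cache;
            # the (U, positions, kernels) intermediate never materialises
            pooled = np.empty((U, d))
            Wc = p["conv_W"].astype(np.float32)
            bc = p["conv_b"].astype(np.float32)
            npos = self._cols.shape[1]
            masks = (np.empty((U, npos, d), dtype=np.uint8)
                     if cache is not None else None)
            for s in range(0, U, self.conv_chunk):
                chunk = u[s:s + self.conv_chunk]
                m = len(chunk)
                pre = self._cols[chunk].reshape(-1, Wc.shape[0]) @ Wc
                pre += bc
                gate = pre > 0
                pre *= gate
                pooled[s:s + m] = pre.reshape(m, npos, d).sum(axis=1) / npos
                if masks is not None:
                    masks[s:s + m] = gate.reshape(m, npos, d)
            toks[:, 0, :] = pooled
            if cache is not None:
                cache["conv_masks"] = masks
        if "net" in self.channels:
            net_pre = feats.net[u] @ p["net_W"] + p["net_b"]
            toks[:, 1, :] = _relu(net_pre)
            if cache is not None:
                cache["net_pre"] = net_pre
        if "bio" in self.channels:
            b1 = _relu(feats.bio[u] @ p["bio_W1"] + p["bio_b1"])
            b2_pre = b1 @ p["bio_W2"] + p["bio_b2"]
            toks[:, 2, :] = _relu(b2_pre)
            if cache is not None:
                cache["bio_h1"] = b1
                cache["bio_pre2"] = b2_pre

        if self.use_attention:
            Q = toks @ p["attn_Q"]
            K = toks @ p["attn_K"]
            V = toks @ p["attn_V"]
            S = Q @ K.transpose(0, 2, 1) / math.sqrt(d)
            A = _softmax_last(S)
            Z = A @ V
            if cache is not None:
                cache.update(toks=toks, Q=Q, K=K, V=V, A=A)
            out = Z.reshape(U, 3 * d)
        else:
            if cache is not None:
                cache.update(toks=toks)
            out = toks.reshape(U, 3 * d)
        if cache is not None:
            cache["u"] = u
        return out

    def _encode_backward(self, dout: np.ndarray, p: dict, g: dict,
                         cache: dict):
        """Backprop from fused representations into all encoder weights."""
        d = self.token_dim
        u = cache["u"]
        U = len(u)
        feats = self.features
        if self.use_attention:
            dZ = dout.reshape(U, 3, d)
            toks, Q, K, V, A = (cache["toks"], cache["Q"], cache["K"],
                                cache["V"], cache["A"])
            dA = dZ @ V.transpose(0, 2, 1)
            dV = A.transpose(0, 2, 1) @ dZ
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dS /= math.sqrt(d)
            dQ = dS @ K
            dK = dS.transpose(0, 2, 1) @ Q
            g["attn_Q"] += np.einsum("utd,ute->de", toks, dQ)
            g["attn_K"] += np.einsum("utd,ute->de", toks, dK)
            g["attn_V"] += np.einsum("utd,ute->de", toks, dV)
            dtoks = (dQ @ p["attn_Q"].T + dK @ p["attn_K"].T
                     + dV @ p["attn_V"].T)
        else:
            dtoks = dout.reshape(U, 3, d)

        if "chem" in self.channels:
            dpool = (dtoks[:, 0, :] / self._cols.shape[1]).astype(np.float32)
            masks = cache["conv_masks"]
            for s in range(0, U, self.conv_chunk):
                chunk = u[s:s + self.conv_chunk]
                m = len(chunk)
                dpre = masks[s:s + m] * dpool[s:s + m][:, None, :]
                g["conv_W"] += np.tensordot(self._cols[chunk], dpre,
                                            axes=([0, 1], [0, 1]))
                g["conv_b"] += dpre.sum(axis=(0, 1))
        if "net" in self.channels:
            dh = dtoks[:, 1, :] * (cache["net_pre"] > 0)
            g["net_W"] += feats.net[u].T @ dh
            g["net_b"] += dh.sum(axis=0)
        if "bio" in self.channels:
            dh2 = dtoks[:, 2, :] * (cache["bio_pre2"] > 0)
            b1 = cache["bio_h1"]
            g["bio_W2"] += b1.T @ dh2
            g["bio_b2"] += dh2.sum(axis=0)
            dh1 = (dh2 @ p["bio_W2"].T) * (b1 > 0)
            g["bio_W1"] += feats.bio[u].T @ dh1
            g["bio_b1"] += dh1.sum(axis=0)

    def _head_forward(self, f: np.ndarray, p: dict, rng=None):
        """Classifier head; dropout applied when ``rng`` is given."""
        n_layers = len(self.hidden) + 1
        h = f
        cache = {"inputs": [], "masks": []}
        keep = 1.0 - self.dropout
        for li in range(n_layers):
            cache["inputs"].append(h)
            pre = h @ p[f"head_W{li}"] + p[f"head_b{li}"]
            if li < n_layers - 1:
                h = _relu(pre)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                h = _sigmoid(pre)
        cache["out"] = h[:, 0]
        return cache

    def _head_backward(self, dlogit: np.ndarray, p: dict, g: dict,
                       cache: dict) -> np.ndarray:
        """``dlogit`` is dLoss/d(pre-sigmoid); returns dLoss/d(input)."""
        n_layers = len(self.hidden) + 1
        delta = dlogit[:, None]
        for li in range(n_layers - 1, -1, -1):
            h_in = cache["inputs"][li]
            g[f"head_W{li}"] += h_in.T @ delta
            g[f"head_b{li}"] += delta.sum(axis=0)
            if li == 0:
                return delta @ p["head_W0"].T
            delta = delta @ p[f"head_W{li}"].T
            mask = cache["masks"][li - 1]
            if mask is not None:
                delta = delta * mask
            # ReLU gate: h_in of the next-shallower layer is its output
            delta = delta * (cache["inputs"][li] > 0)

    def _forward_loss(self, pairs, y, p, rng=None, backward=False):
        """Mean BCE on a batch of (directed) pairs; gradients if asked."""
        u, inv = np.unique(pairs.ravel(), return_inverse=True)
        inv = inv.reshape(pairs.shape)
        enc_cache: dict | None = {} if backward else None
        Z = self._encode_drugs(u, p, enc_cache)
        f = np.concatenate([Z[inv[:, 0]], Z[inv[:, 1]]], axis=1)
        head_cache = self._head_forward(f, p, rng=rng)
        out = np.clip(head_cache["out"], 1e-12, 1 - 1e-12)
        loss = float(-(y * np.log(out) + (1 - y) * np.log(1 - out)).mean())
        if not backward:
            return loss, out, None
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogit = (head_cache["out"] - y) / len(y)
        df = self._head_backward(dlogit, p, g, head_cache)
        w = Z.shape[1]
        dZ = np.zeros_like(Z)
        np.add.at(dZ, inv[:, 0], df[:, :w])
        np.add.at(dZ, inv[:, 1], df[:, w:])
        self._encode_backward(dZ, p, g, enc_cache)
        return loss, out, g

    # ---------------- public API ----------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (n, 2) drug-index pairs with 0/1 labels.

        Both orderings of every training pair are used.  Unless an
        explicit validation set is given, ``val_fraction`` of the pairs is
        held out for early stopping.
        """
        if self.features is None:
            raise ValueError("DDIClassifier requires a DrugFeatures object")
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of drug indices")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training requires both classes present")
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.seed)
        if "chem" in self.channels:
            self._cols = im2col(np.asarray(self.features.chem),
                                self.conv_kernel).astype(np.float32)
        else:
            self._cols = None

        if X_val is None and self.val_fraction > 0 and len(X) >= 20:
            order = rng.permutation(len(X))
            n_val = max(int(round(self.val_fraction * len(X))), 1)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X_tr, y_tr = X[tr_idx], y[tr_idx]
        else:
            X_tr, y_tr = X, y

        # both orderings of every pair
        Xd = np.vstack([X_tr, X_tr[:, ::-1]])
        yd = np.concatenate([y_tr, y_tr])
        if X_val is not None:
            Xv = np.vstack([np.asarray(X_val, dtype=np.int64),
                            np.asarray(X_val, dtype=np.int64)[:, ::-1]])
            yv = np.concatenate([np.asarray(y_val, dtype=np.float64)] * 2)
        else:
            Xv = yv = None

        p = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v2 = {k: np.zeros_like(v) for k, v in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_params = None
        stall = 0
        self.history_ = []
        n = len(Xd)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            nb = 0
            for s in range(0, n, self.batch_size):
                rows = order[s:s + self.batch_size]
                loss, _, g = self._forward_loss(Xd[rows], yd[rows], p,
                                                rng=rng, backward=True)
                ep_loss += loss
                nb += 1
                t += 1
                for k in p:
                    m[k] = b1 * m[k] + (1 - b1) * g[k]
                    v2[k] = b2 * v2[k] + (1 - b2) * g[k] ** 2
                    mhat = m[k] / (1 - b1 ** t)
                    vhat = v2[k] / (1 - b2 ** t)
                    p[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
            rec = {"epoch": epoch, "train_loss": ep_loss / max(nb, 1)}
            if Xv is not None:
                val_loss, _, _ = self._forward_loss(Xv, yv, p)
                rec["val_loss"] = val_loss
                if val_loss < best_val - 1e-5:
                    best_val = val_loss
                    best_params = copy.deepcopy(p)
                    stall = 0
                else:
                    stall += 1
            self.history_.append(rec)
            if Xv is not None and stall >= self.patience:
                break
        self.params_ = best_params if best_params is not None else p
        self.n_features_in_ = 2
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ValueError("DDIClassifier is not fitted")
        if "chem" in self.channels and getattr(self, "_cols", None) is None:
            self._cols = im2col(np.asarray(self.features.chem),
                                self.conv_kernel).astype(np.float32)

    def decision_scores(self, X) -> np.ndarray:
        """Symmetrised interaction probability per pair:
        mean of score(a,b) and score(b,a)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.int64)
        out = np.empty(len(X))
        for s in range(0, len(X), 4096):
            batch = X[s:s + 4096]
            both = np.vstack([batch, batch[:, ::-1]])
            _, scores, _ = self._forward_loss(
                both, np.zeros(len(both)), self.params_)
            k = len(batch)
            out[s:s + 4096] = (scores[:k] + scores[k:]) / 2.0
        return out

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)

    def drug_bundles(self, drug_idx) -> list[DrugFeatureBundle]:
        """Post-reducer channel tokens for the given drug indices."""
        self._check_fitted()
        u = np.asarray(drug_idx, dtype=np.int64)
        cache: dict = {}
        self._encode_drugs(u, self.params_, cache)
        toks = cache["toks"]
        return [DrugFeatureBundle(chem=toks[i, 0], net=toks[i, 1],
                                  bio=toks[i, 2]) for i in range(len(u))]


def train_model(pairs, labels, features: DrugFeatures,
                **config) -> DDIClassifier:
    """Convenience wrapper: construct and fit a :class:`DDIClassifier`."""
    clf = DDIClassifier(features=features, **config)
    return clf.fit(np.asarray(pairs), np.asarray(labels))


def predict_scores(model: DDIClassifier, pairs) -> np.ndarray:
    """Symmetric interaction probabilities for (n, 2) index pairs."""
    return model.decision_scores(np.asarray(pairs))
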