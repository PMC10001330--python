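"""Restricted Boltzmann machines, deep belief networks and an autoencoder.

An RBM is a bipartite energy model over visible units v and hidden units h
with joint probability proportional to ``exp(-E(v, h))``.  For binary
visibles

    E(v, h) = -b_vis' v - b_hid' h - v' W h,

and for real-valued (gaussian) visibles with diagonal precision beta

    E(v, h) = sum_i beta_i (v_i - b_vis_i)^2 / 2 - b_hid' h - (beta * v)' W h,

giving the conditionals  P(h_j = 1 | v) = sigmoid(b_hid_j + W[:, j]' (beta*v))
and v | h ~ N(b_vis + W h, beta^-1)  (sigmoid(b_vis + W h) for binary
visibles).  RBMs are trained by contrastive divergence (CD-k) and stacked
greedily — each machine learns the hidden activations of the one below —
into a deep belief network whose weights initialize a feed-forward sigmoid
network finished by a softmax head and fine-tuned with backpropagation.

The stacked autoencoder is an optional feature compressor: mirrored
sigmoid encoder/decoder trained to minimize mean squared reconstruction
error, whose bottleneck activations can replace the raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit as sigmoid  # numerically stable logistic


@dataclass
class RBMParams:
    W: np.ndarray        # visible x hidden
    b_vis: np.ndarray
    b_hid: np.ndarray
    visible_kind: str = "bernoulli"  # or "gaussian"
    beta: Optional[np.ndarray] = None  # diagonal precision of gaussian visibles

    def __post_init__(self) -> None:
        if self.visible_kind not in ("bernoulli", "gaussian"):
            raise ValueError("visible_kind must be 'bernoulli' or 'gaussian'")
        if self.visible_kind == "gaussian":
            if self.beta is None:
                self.beta = np.ones(self.W.shape[0])
            if np.any(self.beta <= 0):
                raise ValueError("gaussian precision beta must be positive")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


def _visible_drive(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    return v * rbm.beta if rbm.visible_kind == "gaussian" else v


def hidden_activation(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h = 1 | v), elementwise ``sigmoid(b_hid + W' v)``; batched on rows."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != rbm.n_visible:
        raise ValueError(f"expected {rbm.n_visible} visible units, got {v.shape[-1]}")
    return sigmoid(rbm.b_hid + _visible_drive(rbm, v) @ rbm.W)


def visible_activation(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    """Visible conditional given h: probabilities (bernoulli) or means (gaussian)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != rbm.n_hidden:
        raise ValueError(f"expected {rbm.n_hidden} hidden units, got {h.shape[-1]}")
    pre = rbm.b_vis + h @ rbm.W.T
    return sigmoid(pre) if rbm.visible_kind == "bernoulli" else pre


def energy(rbm: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Joint energy E(v, h) of one configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if rbm.visible_kind == "gaussian":
        quad = 0.5 * np.sum(rbm.beta * (v - rbm.b_vis) ** 2)
        return float(quad - rbm.b_hid @ h - (rbm.beta * v) @ rbm.W @ h)
    return float(-rbm.b_vis @ v - rbm.b_hid @ h - v @ rbm.W @ h)


def unnormalized_prob(rbm: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """exp(-E(v, h)), the Boltzmann weight of one joint configuration."""
    return float(np.exp(-energy(rbm, v, h)))


def free_energy(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """F(v) with hidden units summed out; rows of ``v`` are configurations."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    drive = rbm.b_hid + _visible_drive(rbm, v) @ rbm.W
    soft = np.logaddexp(0.0, drive).sum(axis=1)
    if rbm.visible_kind == "gaussian":
        vis = 0.5 * np.sum(rbm.beta * (v - rbm.b_vis) ** 2, axis=1)
        return vis - soft
    return -(v @ rbm.b_vis) - soft


def exact_log_likelihood(rbm: RBMParams, data: np.ndarray) -> float:
    """Average exact log-likelihood for small binary RBMs.

    The partition function is computed by enumerating all visible
    configurations (feasible for roughly <= 20 visible units).
    """
    if rbm.visible_kind != "bernoulli":
        raise ValueError("exact likelihood supported for bernoulli visibles only")
    states = np.array(list(product([0.0, 1.0], repeat=rbm.n_visible)))
    log_z = float(np.logaddexp.reduce(-free_energy(rbm, states)))
    return float(np.mean(-free_energy(rbm, data) - log_z))


def train_rbm_cd(data: np.ndarray, n_hidden: int, k: int = 1, lr: float = 0.05,
                 epochs: int = 10, seed: int = 0, visible_kind: str = "bernoulli",
                 batch_size: int = 32, weight_decay: float = 0.0,
                 init: Optional[RBMParams] = None) -> RBMParams:
    """Contrastive-divergence-k training.

    Positive statistics use the data; negative statistics come from k
    alternating Gibbs steps started at the data (hidden states sampled,
    visible units reconstructed by their conditional mean).  Plain SGD,
    momentum 0, optional L2 weight decay; deterministic per seed.
    """
    if k < 1:
        raise ValueError("CD step count k must be >= 1")
    data = np.asarray(data, dtype=float)
    n, nv = data.shape
    rng = np.random.default_rng(seed)
    if init is not None:
        rbm = RBMParams(W=init.W.copy(), b_vis=init.b_vis.copy(),
                        b_hid=init.b_hid.copy(), visible_kind=visible_kind,
                        beta=None if init.beta is None else init.beta.copy())
    else:
        rbm = RBMParams(W=rng.normal(0.0, 1.0 / np.sqrt(nv), size=(nv, n_hidden)),
                        b_vis=np.zeros(nv), b_hid=np.zeros(n_hidden),
                        visible_kind=visible_kind)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            v0 = data[order[start:start + batch_size]]
            b = v0.shape[0]
            ph0 = hidden_activation(rbm, v0)
            h = (rng.uniform(size=ph0.shape) < ph0).astype(float)
            vk = v0
            for step in range(k):
                vk = visible_activation(rbm, h)
                phk = hidden_activation(rbm, vk)
                if step < k - 1:
                    h = (rng.uniform(size=phk.shape) < phk).astype(float)
            d0 = _visible_drive(rbm, v0)
            dk = _visible_drive(rbm, vk)
            grad_w = (d0.T @ ph0 - dk.T @ phk) / b
            rbm.W += lr * (grad_w - weight_decay * rbm.W)
            rbm.b_vis += lr * np.mean(d0 - dk, axis=0)
            rbm.b_hid += lr * np.mean(ph0 - phk, axis=0)
    return rbm


# ---------------------------------------------------------------------------
# deep belief network

@dataclass
class DBNModel:
    rbms: list
    head_W: np.ndarray   # last hidden dim x n_classes
    head_b: np.ndarray
    n_classes: int


def dbn_forward(rbms: Sequence[RBMParams], X: np.ndarray) -> np.ndarray:
    """Deterministic bottom-up pass: compose the RBM recognition means."""
    h = np.asarray(X, dtype=float)
    for rbm in rbms:
        h = hidden_activation(rbm, h)
    return h


def pretrain_dbn(X: np.ndarray, hidden: Sequence[int], lr: float = 0.05,
                 epochs: int = 10, cd_k: int = 1, seed: int = 0) -> list:
    """Greedy layer-wise pretraining.

    The first machine has gaussian visibles (standardized real features);
    each subsequent machine is binary-binary, trained on the hidden
    probabilities of the layer below.
    """
    rbms = []
    layer_in = np.asarray(X, dtype=float)
    for li, nh in enumerate(hidden):
        kind = "gaussian" if li == 0 else "bernoulli"
        rbm = train_rbm_cd(layer_in, n_hidden=nh, k=cd_k, lr=lr, epochs=epochs,
                           seed=seed + li, visible_kind=kind)
        rbms.append(rbm)
        layer_in = hidden_activation(rbm, layer_in)
    return rbms


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def stack_and_fine_tune(rbms: Sequence[RBMParams], X: np.ndarray, y: np.ndarray,
                        n_classes: int, lr: float = 0.3, epochs: int = 30,
                        seed: int = 0, batch_size: int = 32,
                        head_epochs: int = 50, head_lr: float = 0.5) -> DBNModel:
    """Stack pretrained RBMs into a classifier and fine-tune by backprop.

    The softmax head is first fitted on the frozen top-layer activations
    with its own learning rate (softmax regression is convex, so the
    warmup tolerates a larger step; it also means ``epochs = 0`` yields a
    usable classifier), then the whole network is fine-tuned end to end
    with cross-entropy SGD.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError("labels must lie in [0, n_classes)")
    rng = np.random.default_rng(seed)
    rbms = [RBMParams(W=r.W.copy(), b_vis=r.b_vis.copy(), b_hid=r.b_hid.copy(),
                      visible_kind=r.visible_kind,
                      beta=None if r.beta is None else r.beta.copy())
            for r in rbms]
    d_top = rbms[-1].n_hidden
    head_W = rng.normal(0.0, 0.01, size=(d_top, n_classes))
    head_b = np.zeros(n_classes)
    onehot = np.eye(n_classes)[y]
    n = X.shape[0]

    # head-only warmup on frozen DBN features
    top = dbn_forward(rbms, X)
    for _ in range(head_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            probs = _softmax(top[idx] @ head_W + head_b)
            g = (probs - onehot[idx]) / idx.size
            head_W -= head_lr * top[idx].T @ g
            head_b -= head_lr * g.sum(axis=0)

    # joint fine-tuning through every sigmoid layer
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            acts = [X[idx]]
            for rbm in rbms:
                acts.append(hidden_activation(rbm, acts[-1]))
            probs = _softmax(acts[-1] @ head_W + head_b)
            g = (probs - onehot[idx]) / idx.size
            gW_head = acts[-1].T @ g
            g = g @ head_W.T
            head_W -= lr * gW_head
            head_b -= lr * (probs - onehot[idx]).sum(axis=0) / idx.size
            for li in range(len(rbms) - 1, -1, -1):
                a = acts[li + 1]
                g = g * a * (1.0 - a)  # sigmoid derivative
                drive_in = _visible_drive(rbms[li], acts[li])
                gW = drive_in.T @ g
                gb = g.sum(axis=0)
                g = g @ rbms[li].W.T
                if rbms[li].visible_kind == "gaussian":
                    g = g * rbms[li].beta
                rbms[li].W -= lr * gW
                rbms[li].b_hid -= lr * gb
    return DBNModel(rbms=rbms, head_W=head_W, head_b=head_b, n_classes=n_classes)


def predict(model: DBNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class softmax probabilities and argmax labels."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.rbms[0].n_visible:
        raise ValueError(f"expected {model.rbms[0].n_visible} features, "
                         f"got {X.shape[1]}")
    top = dbn_forward(model.rbms, X)
    probs = _softmax(top @ model.head_W + model.head_b)
    return probs, probs.argmax(axis=1)


def fit_dbn_classifier(X: np.ndarray, y: np.ndarray, n_classes: int,
                       hidden: Sequence[int] = (64, 32), rbm_lr: float = 0.05,
                       rbm_epochs: int = 15, cd_k: int = 1,
                       finetune_lr: float = 0.3, finetune_epochs: int = 30,
                       seed: int = 0) -> DBNModel:
    """Pretrain a stack of RBMs on ``X`` and fine-tune the full classifier."""
    rbms = pretrain_dbn(X, hidden, lr=rbm_lr, epochs=rbm_epochs, cd_k=cd_k,
                        seed=seed)
    return stack_and_fine_tune(rbms, X, y, n_classes, lr=finetune_lr,
                               epochs=finetune_epochs, seed=seed)


def save_model(model: DBNModel, path) -> None:
    """Serialize a DBN to a single portable .npz archive (arrays + JSON)."""
    import json

    arrays = {"head_W": model.head_W, "head_b": model.head_b}
    meta = {"n_classes": model.n_classes, "layers": []}
    for i, rbm in enumerate(model.rbms):
        arrays[f"W_{i}"] = rbm.W
        arrays[f"b_vis_{i}"] = rbm.b_vis
        arrays[f"b_hid_{i}"] = rbm.b_hid
        if rbm.beta is not None:
            arrays[f"beta_{i}"] = rbm.beta
        meta["layers"].append({"visible_kind": rbm.visible_kind,
                               "has_beta": rbm.beta is not None})
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path) -> DBNModel:
    """Inverse of :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        rbms = []
        for i, layer in enumerate(meta["layers"]):
            rbms.append(RBMParams(
                W=npz[f"W_{i}"], b_vis=npz[f"b_vis_{i}"],
                b_hid=npz[f"b_hid_{i}"], visible_kind=layer["visible_kind"],
                beta=npz[f"beta_{i}"] if layer["has_beta"] else None))
        return DBNModel(rbms=rbms, head_W=npz["head_W"], head_b=npz["head_b"],
                        n_classes=meta["n_classes"])


# ---------------------------------------------------------------------------
# stacked autoencoder

@dataclass
class AEModel:
    enc_W: list
    enc_b: list
    dec_W: list
    dec_b: list

    @property
    def bottleneck_dim(self) -> int:
        return self.enc_W[-1].shape[1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for W, b in zip(self.enc_W, self.enc_b):
            h = sigmoid(h @ W + b)
        return h

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        h = self.encode(X)
        last = len(self.dec_W) - 1
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            h = h @ W + b
            if i < last:  # identity on the final reconstruction layer
                h = sigmoid(h)
        return h


def reconstruction_loss(X_rec: np.ndarray, X: np.ndarray) -> float:
    """Summed squared reconstruction error divided by the batch size."""
    X_rec = np.asarray(X_rec, dtype=float)
    X = np.asarray(X, dtype=float)
    return float(np.sum((X_rec - X) ** 2) / X.shape[0])


def train_autoencoder(X: np.ndarray, layer_dims: Sequence[int], lr: float = 0.05,
                      epochs: int = 50, seed: int = 0,
                      batch_size: int = 32) -> AEModel:
    """Train a mirrored sigmoid autoencoder by SGD on the MSE objective.

    ``layer_dims`` runs from the input width down to the bottleneck, e.g.
    ``(64, 32, 8)``; the decoder mirrors it back up, with an identity
    activation on the final (real-valued) reconstruction layer.
    """
    X = np.asarray(X, dtype=float)
    dims = list(layer_dims)
    if dims[0] != X.shape[1]:
        raise ValueError("layer_dims[0] must equal the feature width")
    rng = np.random.default_rng(seed)

    def make(shape_in, shape_out):
        return rng.normal(0.0, 1.0 / np.sqrt(shape_in), size=(shape_in, shape_out))

    enc_W = [make(a, b) for a, b in zip(dims[:-1], dims[1:])]
    enc_b = [np.zeros(b) for b in dims[1:]]
    rdims = dims[::-1]
    dec_W = [make(a, b) for a, b in zip(rdims[:-1], rdims[1:])]
    dec_b = [np.zeros(b) for b in rdims[1:]]
    n = X.shape[0]
    n_enc, n_dec = len(enc_W), len(dec_W)

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = X[order[start:start + batch_size]]
            acts = [xb]
            for W, b in zip(enc_W, enc_b):
                acts.append(sigmoid(acts[-1] @ W + b))
            for i, (W, b) in enumerate(zip(dec_W, dec_b)):
                z = acts[-1] @ W + b
                acts.append(sigmoid(z) if i < n_dec - 1 else z)
            g = 2.0 * (acts[-1] - xb) / xb.shape[0]
            for i in range(n_dec - 1, -1, -1):
                a_in = acts[n_enc + i]
                if i < n_dec - 1:
                    a_out = acts[n_enc + i + 1]
                    g = g * a_out * (1.0 - a_out)
                gW, gb = a_in.T @ g, g.sum(axis=0)
                g = g @ dec_W[i].T
                dec_W[i] -= lr * gW
                dec_b[i] -= lr * gb
            for i in range(n_enc - 1, -1, -1):
                a_out = acts[i + 1]
                g = g * a_out * (1.0 - a_out)
                gW, gb = acts[i].T @ g, g.sum(axis=0)
                g = g @ enc_W[i].T
                enc_W[i] -= lr * gW
                enc_b[i] -= lr * gb
    return AEModel(enc_W=enc_W, enc_b=enc_b, dec_W=dec_W, dec_b=dec_b)
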