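"""MobileNet-style depthwise-separable convolutional feature extraction.

Each block factorizes a standard convolution into a per-channel k x k
spatial filter (depthwise) followed by a 1 x 1 channel mixer (pointwise),
cutting the parameter count from ``k*k*C_in*C_out`` to
``k*k*C_in + C_in*C_out``.  A stack of such blocks with ReLU activations
and global average pooling turns each RGB tile into a fixed-length feature
vector.

Two weight modes are supported.  ``random_fixed`` (default) draws the
filter bank once from a seeded He-scaled normal: the map from pixels to
features is then a deterministic, training-free random projection that
preserves color and texture statistics well enough for a downstream
classifier.  ``trained`` fits the stack briefly on the training split with
a temporary softmax head (plain SGD backpropagation) and discards the head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize

from .preprocess import ImageTile

DEFAULT_BLOCKS = ((3, 16, 1), (16, 32, 2), (32, 64, 1), (64, 64, 2))


@dataclass
class ExtractorConfig:
    input_size: tuple[int, int] = (64, 64)
    blocks: tuple[tuple[int, int, int], ...] = DEFAULT_BLOCKS
    kernel: int = 3
    feature_dim: int = 64
    weights_seed: int = 0
    weights_mode: str = "random_fixed"  # or "trained"
    train_epochs: int = 3
    train_lr: float = 0.05
    train_batch: int = 16

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        for (cin, _, s), (cin2, cout, _) in zip(self.blocks[1:], self.blocks[:-1]):
            if cin != cout:
                raise ValueError("block channel chain is inconsistent")
        for _, _, s in self.blocks:
            if s not in (1, 2):
                raise ValueError("stride must be 1 or 2")
        if self.feature_dim != self.blocks[-1][1]:
            raise ValueError("feature_dim must equal the last block's out_channels "
                             "(global average pooling)")
        if self.weights_mode not in ("random_fixed", "trained"):
            raise ValueError("weights_mode must be 'random_fixed' or 'trained'")


@dataclass
class FeatureMatrix:
    """n_samples x feature_dim matrix with optional standardization state."""

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    ids: Optional[np.ndarray] = None
    mean: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# convolution primitives (CHW layout)

def _dw_windows(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Sliding k x k windows of a zero-padded CHW map, strided."""
    pad = kernel // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kernel, kernel), axis=(1, 2))
    return win[:, ::stride, ::stride]


def depthwise_separable_block(feature_map: np.ndarray, params: dict,
                              stride: int = 1) -> np.ndarray:
    """Depthwise k x k conv, ReLU, pointwise 1 x 1 conv, ReLU.

    ``params`` holds ``dw`` (C_in, k, k), ``dw_bias`` (C_in,), ``pw``
    (C_out, C_in) and ``pw_bias`` (C_out,).  "Same" zero padding; stride
    applies to the depthwise stage.
    """
    dw, pw = params["dw"], params["pw"]
    cin = feature_map.shape[0]
    if dw.shape[0] != cin:
        raise ValueError(f"depthwise filters expect {dw.shape[0]} channels, got {cin}")
    if pw.shape[1] != cin:
        raise ValueError(f"pointwise weights expect {pw.shape[1]} channels, got {cin}")
    win = _dw_windows(feature_map, dw.shape[1], stride)
    z = np.einsum("chwij,cij->chw", win, dw) + params["dw_bias"][:, None, None]
    a = np.maximum(z, 0.0)
    z2 = np.tensordot(pw, a, axes=([1], [0])) + params["pw_bias"][:, None, None]
    return np.maximum(z2, 0.0)


def separable_parameter_count(kernel: int, cin: int, cout: int) -> tuple[int, int]:
    """(depthwise-separable, standard) weight counts for one block."""
    return kernel * kernel * cin + cin * cout, kernel * kernel * cin * cout


class FeatureExtractor:
    """A small stack of depthwise-separable blocks with a GAP head."""

    def __init__(self, cfg: ExtractorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.weights_seed)
        k = cfg.kernel
        self.params: list[dict] = []
        for cin, cout, stride in cfg.blocks:
            self.params.append({
                "dw": rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(cin, k, k)),
                "dw_bias": np.zeros(cin),
                "pw": rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)),
                "pw_bias": np.zeros(cout),
                "stride": stride,
            })

    # -- forward ------------------------------------------------------------

    def _prepare(self, tile: ImageTile) -> np.ndarray:
        px = tile.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("extractor requires RGB input")
        h, w = self.cfg.input_size
        img = px.astype(float) / 255.0
        if px.shape[:2] != (h, w):
            img = _sk_resize(img, (h, w), order=1, anti_aliasing=False,
                             preserve_range=True)
        return np.transpose(img - 0.5, (2, 0, 1))  # CHW, centered

    def forward(self, x: np.ndarray) -> np.ndarray:
        for p in self.params:
            x = depthwise_separable_block(x, p, stride=p["stride"])
        return x.mean(axis=(1, 2))  # global average pool

    def transform(self, tiles: Sequence[ImageTile]) -> np.ndarray:
        return np.stack([self.forward(self._prepare(t)) for t in tiles])

    # -- optional brief supervised training ---------------------------------

    def _forward_cached(self, x: np.ndarray):
        cache = []
        for p in self.params:
            k, s = p["dw"].shape[1], p["stride"]
            win = _dw_windows(x, k, s)
            z = np.einsum("chwij,cij->chw", win, p["dw"]) + p["dw_bias"][:, None, None]
            a = np.maximum(z, 0.0)
            z2 = np.tensordot(p["pw"], a, axes=([1], [0])) + p["pw_bias"][:, None, None]
            a2 = np.maximum(z2, 0.0)
            cache.append({"x": x, "win": win, "z": z, "a": a, "z2": z2})
            x = a2
        feat = x.mean(axis=(1, 2))
        return feat, x.shape[1:], cache

    def _backward(self, g_feat: np.ndarray, out_hw: tuple[int, int],
                  cache: list, lr: float) -> None:
        g = np.broadcast_to(g_feat[:, None, None] / (out_hw[0] * out_hw[1]),
                            (g_feat.size, *out_hw)).copy()
        for p, c in zip(reversed(self.params), reversed(cache)):
            g = g * (c["z2"] > 0)
            d_pw = np.einsum("ohw,chw->oc", g, c["a"])
            d_pwb = g.sum(axis=(1, 2))
            g = np.tensordot(p["pw"].T, g, axes=([1], [0]))
            g = g * (c["z"] > 0)
            d_dw = np.einsum("cij,cijuv->cuv", g, c["win"])
            d_dwb = g.sum(axis=(1, 2))
            # scatter gradient back through the strided depthwise conv
            k, s = p["dw"].shape[1], p["stride"]
            pad = k // 2
            cin, hin, win_ = c["x"].shape
            ho, wo = g.shape[1:]
            g_xp = np.zeros((cin, hin + 2 * pad, win_ + 2 * pad))
            for u in range(k):
                for v in range(k):
                    g_xp[:, u:u + s * ho:s, v:v + s * wo:s] += (
                        g * p["dw"][:, u, v][:, None, None])
            p["pw"] -= lr * d_pw
            p["pw_bias"] -= lr * d_pwb
            p["dw"] -= lr * d_dw
            p["dw_bias"] -= lr * d_dwb
            g = g_xp[:, pad:pad + hin, pad:pad + win_]

    def fit(self, tiles: Sequence[ImageTile], labels: np.ndarray) -> None:
        """Brief supervised fit with a throwaway linear softmax head."""
        cfg = self.cfg
        rng = np.random.default_rng(cfg.weights_seed + 1)
        classes = np.unique(labels)
        y = np.searchsorted(classes, labels)
        d, K = cfg.feature_dim, classes.size
        w_head = rng.normal(0.0, 1.0 / np.sqrt(d), size=(K, d))
        b_head = np.zeros(K)
        inputs = [self._prepare(t) for t in tiles]
        n = len(inputs)
        for _ in range(cfg.train_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.train_batch):
                idx = order[start:start + cfg.train_batch]
                gw = np.zeros_like(w_head)
                gb = np.zeros_like(b_head)
                for i in idx:
                    feat, out_hw, cache = self._forward_cached(inputs[i])
                    logits = w_head @ feat + b_head
                    logits -= logits.max()
                    probs = np.exp(logits)
                    probs /= probs.sum()
                    g_logit = probs.copy()
                    g_logit[y[i]] -= 1.0
                    g_logit /= idx.size
                    gw += np.outer(g_logit, feat)
                    gb += g_logit
                    self._backward(w_head.T @ g_logit, out_hw, cache,
                                   cfg.train_lr)
                w_head -= cfg.train_lr * gw
                b_head -= cfg.train_lr * gb


def extract_features(tiles: Sequence[ImageTile], cfg: ExtractorConfig | None = None,
                     fit_labels: Optional[np.ndarray] = None,
                     fit_rows: Optional[np.ndarray] = None) -> FeatureMatrix:
    """Map tiles to an n x feature_dim matrix.

    With ``weights_mode='trained'`` the extractor is first fitted on the
    rows named by ``fit_rows`` (labels from ``fit_labels``); only those rows
    ever influence the weights, so held-out data cannot leak in.
    """
    if len(tiles) == 0:
        raise ValueError("no tiles to extract features from")
    cfg = cfg or ExtractorConfig()
    extractor = FeatureExtractor(cfg)
    labels = np.array([t.label for t in tiles], dtype=object)
    if cfg.weights_mode == "trained":
        lbls = labels if fit_labels is None else np.asarray(fit_labels, dtype=object)
        rows = np.arange(len(tiles)) if fit_rows is None else np.asarray(fit_rows)
        extractor.fit([tiles[i] for i in rows], lbls[rows])
    values = extractor.transform(tiles)
    return FeatureMatrix(values=values, labels=labels,
                         ids=np.array([t.source_id for t in tiles], dtype=object))


def standardize(features: FeatureMatrix, fit_rows: Sequence[int]) -> FeatureMatrix:
    """Per-feature z-scoring with statistics from ``fit_rows`` only.

    Zero-variance features map to exactly 0 for every row.
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    sub = features.values[fit_rows]
    mean = sub.mean(axis=0)
    scale = sub.std(axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    values = (features.values - mean) / safe
    values[:, scale == 0] = 0.0
    return FeatureMatrix(values=values, labels=features.labels, ids=features.ids,
                         mean=mean, scale=scale)
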