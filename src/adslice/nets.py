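"""Minimal convolutional network primitives (numpy, explicit backprop).

Provides the ``tiny_cnn`` backbone used by the slice classifier: two
3x3-conv + batch-norm + ReLU + 2x2-max-pool stages followed by a fully
connected projection (also batch-normalized) to a fixed-length feature
vector.  Batch normalization is affine-free and mirrors the conditioning
role it plays in the modern convolutional backbone families; running
statistics are kept for inference.  Any backbone honoring the
``image -> (feature_dim,) vector`` contract can stand in; the classifier
head and all downstream ensembling are backbone-agnostic.

Internals use channels-last (NHWC) layout and strided im2col views so the
heavy lifting is done by BLAS matrix products; convolution weights are
stored directly as ``(9 * c_in, c_out)`` matrices.  All parameters live in
a flat ``dict[str, ndarray]`` so snapshotting the best-epoch weights and
applying optimizer updates stay trivial.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["conv3x3_im2col", "maxpool2_nhwc", "TinyCNNBackbone"]

BN_EPS = 1e-5
BN_MOMENTUM = 0.8


def conv3x3_im2col(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9*C) same-padded 3x3 patch matrix."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    sn, sh, sw, sc = xp.strides
    view = as_strided(xp, shape=(n, h, w, 3, 3, c), strides=(sn, sh, sw, sh, sw, sc))
    return view.reshape(n * h * w, 9 * c)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    n, h, w, c = shape
    d6 = dcols.reshape(n, h, w, 3, 3, c)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += d6[:, :, :, di, dj, :]
    return dxp[:, 1 : h + 1, 1 : w + 1, :]


def maxpool2_nhwc(x: np.ndarray):
    """2x2 max pooling on (N,H,W,C); returns (pooled, unpool)."""
    quads = (
        x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]
    )
    y = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))

    def unpool(dy):
        dx = np.zeros_like(x)
        taken = np.zeros(dy.shape, dtype=bool)
        for (si, sj), q in zip(((0, 0), (0, 1), (1, 0), (1, 1)), quads):
            hit = (q == y) & ~taken  # ties: gradient to the first maximum
            dx[:, si::2, sj::2] += np.where(hit, dy, 0)
            taken |= hit
        return dx

    return y, unpool


def _bn_forward(x2d: np.ndarray, running: dict, key: str, train: bool, acc=None):
    """Affine-free batch norm over axis 0 of a (M, C) view."""
    if train:
        mu = x2d.mean(axis=0)
        var = x2d.var(axis=0)
        if acc is not None:
            acc[key].append((mu, var))
        else:
            running[key + "_mean"] = (
                BN_MOMENTUM * running[key + "_mean"] + (1 - BN_MOMENTUM) * mu
            )
            running[key + "_var"] = (
                BN_MOMENTUM * running[key + "_var"] + (1 - BN_MOMENTUM) * var
            )
    else:
        mu = running[key + "_mean"]
        var = running[key + "_var"]
    inv = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x2d - mu) * inv
    return xhat.astype(x2d.dtype), (xhat, inv)


def _bn_backward(dy2d: np.ndarray, cache) -> np.ndarray:
    xhat, inv = cache
    m = dy2d.shape[0]
    return (inv / m) * (
        m * dy2d - dy2d.sum(axis=0) - xhat * (dy2d * xhat).sum(axis=0)
    ).astype(dy2d.dtype)


class TinyCNNBackbone:
    """[conv3x3 -> BN -> ReLU -> pool] x2 -> FC -> BN -> ReLU feature vector."""

    def __init__(
        self,
        input_px: int,
        feature_dim: int,
        channels: tuple[int, int] = (16, 32),
        in_channels: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if input_px % 4 != 0:
            raise ValueError("input_px must be divisible by 4 (two 2x2 pools)")
        rng = rng or np.random.default_rng(0)
        c1, c2 = channels
        self.input_px = input_px
        self.feature_dim = int(feature_dim)
        self.channels = (c1, c2)
        self.in_channels = in_channels
        self.flat_dim = c2 * (input_px // 4) ** 2
        self.dtype = dtype

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)

        self.params = {
            "conv1_w": he((9 * in_channels, c1), in_channels * 9),
            "conv2_w": he((9 * c1, c2), c1 * 9),
            "fc_w": he((self.flat_dim, self.feature_dim), self.flat_dim),
        }
        # BN running statistics (state, not trainable parameters)
        self.state = {}
        for key, dim in (("bn1", c1), ("bn2", c2), ("bnf", self.feature_dim)):
            self.state[key + "_mean"] = np.zeros(dim, dtype=np.float64)
            self.state[key + "_var"] = np.ones(dim, dtype=np.float64)

    def forward(self, x: np.ndarray, want_cache: bool = False, train: bool = False):
        """x: (N, in_channels, px, px) -> features (N, feature_dim)."""
        p = self.params
        n = x.shape[0]
        h = w = self.input_px
        acc = getattr(self, "_bn_acc", None)
        xh = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=self.dtype)

        cols1 = conv3x3_im2col(xh)
        z1 = cols1 @ p["conv1_w"]
        b1, bn1c = _bn_forward(z1, self.state, "bn1", train, acc)
        a1 = np.maximum(b1, 0).reshape(n, h, w, -1)
        p1, unpool1 = maxpool2_nhwc(a1)

        cols2 = conv3x3_im2col(p1)
        z2 = cols2 @ p["conv2_w"]
        b2, bn2c = _bn_forward(z2, self.state, "bn2", train, acc)
        a2 = np.maximum(b2, 0).reshape(n, h // 2, w // 2, -1)
        p2, unpool2 = maxpool2_nhwc(a2)

        flat = p2.reshape(n, -1)
        zf = flat @ p["fc_w"]
        bf, bnfc = _bn_forward(zf, self.state, "bnf", train, acc)
        feat = np.maximum(bf, 0)
        if not want_cache:
            return feat
        cache = (p1.shape, cols1, cols2, b1, b2, flat, bf,
                 bn1c, bn2c, bnfc, unpool1, unpool2)
        return feat, cache

    def start_bn_recalibration(self) -> None:
        """Begin collecting batch statistics instead of EMA updates."""
        self._bn_acc = {"bn1": [], "bn2": [], "bnf": []}

    def finish_bn_recalibration(self) -> None:
        """Replace running statistics with exact moments of the collected pass.

        The population variance combines the mean within-batch variance and
        the between-batch variance of the means.
        """
        for key, entries in self._bn_acc.items():
            mus = np.stack([m for m, _ in entries])
            vrs = np.stack([v for _, v in entries])
            self.state[key + "_mean"] = mus.mean(axis=0)
            self.state[key + "_var"] = vrs.mean(axis=0) + mus.var(axis=0)
        self._bn_acc = None

    def backward(self, dfeat: np.ndarray, cache) -> dict:
        """Parameter gradients (input gradients are not propagated past conv1)."""
        p = self.params
        (p1_shape, cols1, cols2, b1, b2, flat, bf,
         bn1c, bn2c, bnfc, unpool1, unpool2) = cache
        n = dfeat.shape[0]

        dbf = dfeat * (bf > 0)
        dzf = _bn_backward(dbf, bnfc)
        grads = {"fc_w": flat.T @ dzf}
        dflat = dzf @ p["fc_w"].T

        c2 = self.channels[1]
        hw2 = self.input_px // 2
        da2 = unpool2(dflat.reshape(n, hw2 // 2, hw2 // 2, c2))
        db2 = da2.reshape(-1, c2) * (b2 > 0)
        dz2 = _bn_backward(db2, bn2c)
        grads["conv2_w"] = cols2.T @ dz2
        dcols2 = dz2 @ p["conv2_w"].T
        dp1 = _col2im(dcols2, p1_shape)

        c1 = self.channels[0]
        da1 = unpool1(dp1)
        db1 = da1.reshape(-1, c1) * (b1 > 0)
        dz1 = _bn_backward(db1, bn1c)
        grads["conv1_w"] = cols1.T @ dz1
        return grads
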