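"""A small 3D convolutional network implemented directly on numpy.

The network is the classifier used throughout the package: two stride-2
"same"-padded 3D convolutions (leaky-ReLU, 2x2x2 ceil-mode max pooling after
each), a 1024-unit fully connected layer with dropout, and a 2-way softmax.
Convolutions are evaluated as im2col + BLAS GEMM in float32, which on a
single CPU core trains the default 160k-parameter model on thousands of
ROIs per second-scale epochs.  All randomness (weight init, dropout,
shuffling) flows through numpy Generators, so training is deterministic
given a seed.

Layout convention: activations are channels-last ``(N, D, H, W, C)`` with
``(D, H, W)`` = (z, y, x); kernels are ``(Cin, kd, kh, kw, Cout)``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def same_pad(in_size: int, k: int, s: int) -> tuple[int, int, int]:
    """TF-style 'same' padding: output = ceil(in/s), extra padding at the end."""
    out = math.ceil(in_size / s)
    total = max((out - 1) * s + k - in_size, 0)
    before = total // 2
    return out, before, total - before


def _im2col(x: np.ndarray, kernel: Sequence[int], stride: Sequence[int]):
    """Return (cols, out_shape): cols is (N*P, C*kd*kh*kw), P = prod(out_shape)."""
    n, d, h, w, c = x.shape
    kd, kh, kw = kernel
    sd, sh, sw = stride
    do, pd0, pd1 = same_pad(d, kd, sd)
    ho, ph0, ph1 = same_pad(h, kh, sh)
    wo, pw0, pw1 = same_pad(w, kw, sw)
    xp = np.pad(x, ((0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1), (0, 0)))
    sw_view = sliding_window_view(xp, (kd, kh, kw), axis=(1, 2, 3))
    sw_view = sw_view[:, ::sd, ::sh, ::sw]  # (N, Do, Ho, Wo, C, kd, kh, kw)
    cols = sw_view.reshape(n * do * ho * wo, c * kd * kh * kw)
    return np.ascontiguousarray(cols, dtype=np.float32), (do, ho, wo), (pd0, ph0, pw0), xp.shape


class Conv3dSame:
    """Stride-s 'same' 3D convolution, im2col + GEMM."""

    def __init__(self, c_in, c_out, kernel, stride, rng):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        fan_in = c_in * int(np.prod(kernel))
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, cache=None):
        cols, out_sp, pads, xp_shape = _im2col(x, self.kernel, self.stride)
        n = x.shape[0]
        y = cols @ self.W + self.b
        y = y.reshape(n, *out_sp, self.W.shape[1])
        if cache is not None:
            cache["cols"] = cols
            cache["x_shape"] = x.shape
            cache["pads"] = pads
            cache["xp_shape"] = xp_shape
            cache["out_sp"] = out_sp
        return y

    def backward(self, dy, cache, need_dx: bool):
        n, do, ho, wo, c_out = dy.shape
        dy2 = np.ascontiguousarray(dy.reshape(-1, c_out))
        dW = cache["cols"].T @ dy2
        db = dy2.sum(axis=0)
        dx = None
        if need_dx:
            kd, kh, kw = self.kernel
            sd, sh, sw = self.stride
            c_in = cache["x_shape"][4]
            dcols = (dy2 @ self.W.T).reshape(n, do, ho, wo, c_in, kd, kh, kw)
            dxp = np.zeros(cache["xp_shape"], dtype=np.float32)
            for a in range(kd):
                for b in range(kh):
                    for c in range(kw):
                        dxp[
                            :,
                            a : a + sd * do : sd,
                            b : b + sh * ho : sh,
                            c : c + sw * wo : sw,
                            :,
                        ] += dcols[:, :, :, :, :, a, b, c]
            pd0, ph0, pw0 = cache["pads"]
            _, d, h, w, _ = cache["x_shape"]
            dx = dxp[:, pd0 : pd0 + d, ph0 : ph0 + h, pw0 : pw0 + w, :]
        return dW, db, dx


class MaxPoolCeil2:
    """2x2x2 max pooling with ceil-mode output (odd extents are padded)."""

    def forward(self, x, cache=None):
        n, d, h, w, c = x.shape
        dp, hp, wp = (-d) % 2, (-h) % 2, (-w) % 2
        xp = np.pad(
            x,
            ((0, 0), (0, dp), (0, hp), (0, wp), (0, 0)),
            constant_values=-np.inf,
        )
        do, ho, wo = xp.shape[1] // 2, xp.shape[2] // 2, xp.shape[3] // 2
        blocks = (
            xp.reshape(n, do, 2, ho, 2, wo, 2, c)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(n, do, ho, wo, c, 8)
        )
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if cache is not None:
            cache["idx"] = idx
            cache["x_shape"] = x.shape
            cache["xp_shape"] = xp.shape
        return out

    def backward(self, dy, cache):
        n, dpad, hpad, wpad, c = cache["xp_shape"]
        do, ho, wo = dpad // 2, hpad // 2, wpad // 2
        dblocks = np.zeros((n, do, ho, wo, c, 8), dtype=np.float32)
        np.put_along_axis(dblocks, cache["idx"][..., None], dy[..., None], axis=-1)
        dxp = (
            dblocks.reshape(n, do, ho, wo, c, 2, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(n, dpad, hpad, wpad, c)
        )
        _, d, h, w, _ = cache["x_shape"]
        return dxp[:, :d, :h, :w, :]


def _leaky(x, slope):
    y = x * slope
    np.maximum(x, y, out=y)
    return y


def _dleaky_mul(dy, x, slope):
    """dy * leaky'(x) without boolean where (hot path)."""
    m = (x > 0).astype(np.float32)
    m *= np.float32(1.0) - slope
    m += slope
    m *= dy
    return m


class ConvNet3D:
    """Two-conv-layer 3D network for binary voxel-ROI classification.

    Parameters are created by He-style seeded initialization.  ``cfg`` is any
    object exposing kernels_layer1, kernels_layer2, kernel_zyx, stride, pool,
    fc_units, dropout, leaky_slope, learning_rate and seed.
    """

    INPUT_SHAPE = (8, 28, 28)

    def __init__(self, cfg):
        self.cfg = cfg
        k2 = cfg.kernels_layer2 or 2 * cfg.kernels_layer1
        rng = np.random.default_rng(cfg.seed)
        self.conv1 = Conv3dSame(1, cfg.kernels_layer1, cfg.kernel_zyx, cfg.stride, rng)
        self.pool1 = MaxPoolCeil2()
        self.conv2 = Conv3dSame(cfg.kernels_layer1, k2, cfg.kernel_zyx, cfg.stride, rng)
        self.pool2 = MaxPoolCeil2()
        trace = self.shape_trace()
        if min(trace[-1]) < 1:
            raise ValueError(f"config produces non-positive spatial dims: {trace}")
        self.flat_dim = int(np.prod(trace[-1])) * k2
        self.Wf = rng.normal(
            0.0, math.sqrt(2.0 / self.flat_dim), size=(self.flat_dim, cfg.fc_units)
        ).astype(np.float32)
        self.bf = np.zeros(cfg.fc_units, dtype=np.float32)
        self.Wo = rng.normal(
            0.0, math.sqrt(2.0 / cfg.fc_units), size=(cfg.fc_units, 2)
        ).astype(np.float32)
        self.bo = np.zeros(2, dtype=np.float32)
        self._adam_state: dict | None = None
        self._adam_t = 0

    # --- introspection -------------------------------------------------
    def shape_trace(self) -> list[tuple[int, int, int]]:
        """Spatial extents (z, y, x) after input, conv1, pool1, conv2, pool2."""
        shp = self.INPUT_SHAPE
        trace = [shp]
        for _ in range(2):
            shp = tuple(
                same_pad(s, k, st)[0]
                for s, k, st in zip(shp, self.cfg.kernel_zyx, self.cfg.stride)
            )
            trace.append(shp)
            shp = tuple(math.ceil(s / p) for s, p in zip(shp, self.cfg.pool))
            trace.append(shp)
        return trace

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.conv1.W,
            "b1": self.conv1.b,
            "W2": self.conv2.W,
            "b2": self.conv2.b,
            "Wf": self.Wf,
            "bf": self.bf,
            "Wo": self.Wo,
            "bo": self.bo,
        }

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters().values()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(weights) != set(params):
            raise ValueError("weight name mismatch")
        for k, v in weights.items():
            if params[k].shape != v.shape:
                raise ValueError(
                    f"topology mismatch for {k}: {params[k].shape} vs {v.shape}"
                )
            params[k][...] = v
        self._adam_state = None
        self._adam_t = 0

    # --- forward / backward --------------------------------------------
    def _forward(self, x, train=False, rng=None, cache=None):
        if x.ndim == 4:  # (N, z, y, x) -> channels-last
            x = x[..., None]
        x = np.ascontiguousarray(x, dtype=np.float32)
        slope = np.float32(self.cfg.leaky_slope)
        c1 = {} if cache is not None else None
        z1 = self.conv1.forward(x, c1)
        a1 = _leaky(z1, slope)
        p1c = {} if cache is not None else None
        p1 = self.pool1.forward(a1, p1c)
        c2 = {} if cache is not None else None
        z2 = self.conv2.forward(p1, c2)
        a2 = _leaky(z2, slope)
        p2c = {} if cache is not None else None
        p2 = self.pool2.forward(a2, p2c)
        flat = p2.reshape(p2.shape[0], -1)
        zf = flat @ self.Wf + self.bf
        af = _leaky(zf, slope)
        if train and self.cfg.dropout > 0:
            keep = np.float32(1.0 - self.cfg.dropout)
            mask = (rng.random(af.shape, dtype=np.float32) < keep).astype(
                np.float32
            ) / keep
            ad = af * mask
        else:
            mask = None
            ad = af
        logits = ad @ self.Wo + self.bo
        if cache is not None:
            cache.update(
                x=x, c1=c1, z1=z1, p1c=p1c, p1=p1, c2=c2, z2=z2, p2c=p2c,
                p2_shape=p2.shape, flat=flat, zf=zf, ad=ad, mask=mask,
            )
        return logits

    def loss_and_grads(self, x, y, rng):
        """Mean softmax cross-entropy and gradients for one minibatch."""
        cache: dict = {}
        logits = self._forward(x, train=True, rng=rng, cache=cache)
        n = x.shape[0]
        logits64 = logits.astype(np.float64)
        logits64 -= logits64.max(axis=1, keepdims=True)
        e = np.exp(logits64)
        p = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())

        slope = np.float32(self.cfg.leaky_slope)
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits = (dlogits / n).astype(np.float32)
        dWo = cache["ad"].T @ dlogits
        dbo = dlogits.sum(axis=0)
        dad = dlogits @ self.Wo.T
        if cache["mask"] is not None:
            dad = dad * cache["mask"]
        dzf = _dleaky_mul(dad, cache["zf"], slope)
        dWf = cache["flat"].T @ dzf
        dbf = dzf.sum(axis=0)
        dflat = dzf @ self.Wf.T
        dp2 = dflat.reshape(cache["p2_shape"])
        da2 = self.pool2.backward(dp2, cache["p2c"])
        dz2 = _dleaky_mul(da2, cache["z2"], slope)
        dW2, db2, dp1 = self.conv2.backward(dz2, cache["c2"], need_dx=True)
        da1 = self.pool1.backward(dp1, cache["p1c"])
        dz1 = _dleaky_mul(da1, cache["z1"], slope)
        dW1, db1, _ = self.conv1.backward(dz1, cache["c1"], need_dx=False)
        grads = {
            "W1": dW1, "b1": db1, "W2": dW2, "b2": db2,
            "Wf": dWf, "bf": dbf, "Wo": dWo, "bo": dbo,
        }
        return loss, grads

    def adam_step(self, grads, lr=None, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self.parameters()
        if self._adam_state is None:
            self._adam_state = {
                k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()
            }
        self._adam_t += 1
        t = self._adam_t
        lr = np.float32(self.cfg.learning_rate if lr is None else lr)
        bc1 = 1.0 - beta1**t
        bc2 = 1.0 - beta2**t
        for k, p in params.items():
            g = grads[k]
            m, v = self._adam_state[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)

    def predict_proba(self, x, batch_size: int = 512) -> np.ndarray:
        """Class probabilities; dropout disabled, deterministic."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self._forward(x[i : i + batch_size].astype(np.float32))
            logits = logits.astype(np.float64)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)
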