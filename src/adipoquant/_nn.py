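"""Minimal numpy implementation of a small U-style encoder-decoder.

Deliberately dependency-free (no GPU frameworks): 3x3 convolutions via
nine shifted einsums, 2x2 max pooling, nearest-neighbor upsampling, skip
concatenation, Adam, and binary cross-entropy with logits. Everything is
float64 and fully deterministic given the seed, which is what the
checkpoint round-trip and reproducibility contracts require.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyUNet", "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all elements; returns (loss, dloss/dz)."""
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - t) / z.size
    return float(loss.mean()), dz


class _Conv3x3:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = rng.standard_normal((cout, cin, 3, 3)) * scale
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        out = np.zeros((B, self.W.shape[0], H, W))
        for di in range(3):
            for dj in range(3):
                out += np.einsum(
                    "oc,bchw->bohw", self.W[:, :, di, dj], xp[:, :, di : di + H, dj : dj + W]
                )
        return out + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, _, H, W = dy.shape
        self.db = dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, :, di : di + H, dj : dj + W]
                self.dW[:, :, di, dj] = np.einsum("bohw,bchw->oc", dy, patch)
                dxp[:, :, di : di + H, dj : dj + W] += np.einsum(
                    "oc,bohw->bchw", self.W[:, :, di, dj], dy
                )
        return dxp[:, :, 1:-1, 1:-1]


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _pool2_fwd(x):
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
    m = xr.max(axis=(3, 5), keepdims=True)
    mask = (xr == m).astype(np.float64)
    mask /= mask.sum(axis=(3, 5), keepdims=True)  # split gradient on ties
    return m.reshape(B, C, H // 2, W // 2), mask


def _pool2_bwd(dy, mask):
    B, C, Hh, Ww = dy.shape
    return (dy.reshape(B, C, Hh, 1, Ww, 1) * mask).reshape(B, C, Hh * 2, Ww * 2)


def _up2_fwd(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_bwd(dy):
    B, C, H, W = dy.shape
    return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class TinyUNet:
    """Depth-2 encoder-decoder with skip connections and 3 output channels.

    Input (B, 1, H, W) with H, W divisible by 4; output logits (B, 3, H, W).
    """

    def __init__(self, base_channels: int = 8, out_channels: int = 3, seed: int = 0):
        c = base_channels
        rng = np.random.default_rng(seed)
        self.base_channels = c
        self.out_channels = out_channels
        self.conv_e1 = _Conv3x3(1, c, rng)
        self.conv_e2 = _Conv3x3(c, 2 * c, rng)
        self.conv_bot = _Conv3x3(2 * c, 2 * c, rng)
        self.conv_d2 = _Conv3x3(4 * c, c, rng)
        self.conv_d1 = _Conv3x3(2 * c, c, rng)
        self.conv_out = _Conv3x3(c, out_channels, rng)
        self._convs = [
            self.conv_e1,
            self.conv_e2,
            self.conv_bot,
            self.conv_d2,
            self.conv_d1,
            self.conv_out,
        ]
        self._cache: dict = {}

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for conv in self._convs:
            out.extend([conv.W, conv.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for conv in self._convs:
            out.extend([conv.dW, conv.db])
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ["e1", "e2", "bot", "d2", "d1", "out"]
        state = {}
        for name, conv in zip(names, self._convs):
            state[f"{name}.W"] = conv.W
            state[f"{name}.b"] = conv.b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        names = ["e1", "e2", "bot", "d2", "d1", "out"]
        for name, conv in zip(names, self._convs):
            conv.W = np.array(state[f"{name}.W"], dtype=np.float64)
            conv.b = np.array(state[f"{name}.b"], dtype=np.float64)
            conv.dW = np.zeros_like(conv.W)
            conv.db = np.zeros_like(conv.b)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        cache = self._cache
        e1, cache["m1"] = _relu_fwd(self.conv_e1.forward(x))
        p1, cache["pm1"] = _pool2_fwd(e1)
        e2, cache["m2"] = _relu_fwd(self.conv_e2.forward(p1))
        p2, cache["pm2"] = _pool2_fwd(e2)
        bot, cache["mb"] = _relu_fwd(self.conv_bot.forward(p2))
        u2 = _up2_fwd(bot)
        d2, cache["md2"] = _relu_fwd(self.conv_d2.forward(np.concatenate([u2, e2], axis=1)))
        u1 = _up2_fwd(d2)
        d1, cache["md1"] = _relu_fwd(self.conv_d1.forward(np.concatenate([u1, e1], axis=1)))
        cache["c2"] = 2 * self.base_channels
        cache["c1"] = self.base_channels
        return self.conv_out.forward(d1)

    def backward(self, dlogits: np.ndarray) -> None:
        cache = self._cache
        dd1 = self.conv_out.backward(dlogits) * cache["md1"]
        dcat1 = self.conv_d1.backward(dd1)
        du1, de1_skip = dcat1[:, : cache["c1"]], dcat1[:, cache["c1"] :]
        dd2 = _up2_bwd(du1) * cache["md2"]
        dcat2 = self.conv_d2.backward(dd2)
        du2, de2_skip = dcat2[:, : cache["c2"]], dcat2[:, cache["c2"] :]
        dbot = _up2_bwd(du2) * cache["mb"]
        dp2 = self.conv_bot.backward(dbot)
        de2 = _pool2_bwd(dp2, cache["pm2"]) * cache["m2"] + de2_skip * cache["m2"]
        dp1 = self.conv_e2.backward(de2)
        de1 = _pool2_bwd(dp1, cache["pm1"]) * cache["m1"] + de1_skip * cache["m1"]
        self.conv_e1.backward(de1)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
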