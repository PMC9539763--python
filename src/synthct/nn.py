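"""Minimal NumPy neural-network core for the desk-scale translation networks.

Implements exactly what the image-translation pipeline needs — strided 2D
convolutions (im2col), nearest-neighbour upsampling, leaky-ReLU/tanh, a U-Net
generator with skip connections, a patch-wise convolutional discriminator,
and an Adam optimizer — with explicit forward/backward passes so training is
a pure, bit-reproducible function of the seed. Arrays are (channels, H, W)
float32 single planes; batching is handled by the caller accumulating
gradients across planes before an optimizer step.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["Conv2d", "UNetGenerator", "PatchDiscriminator", "Adam",
           "save_checkpoint", "load_checkpoint"]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(c * k * k, oh * ow), (oh, ow)


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    c, h, w = x_shape
    gxp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g = gcols.reshape(c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            gxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride] += g[:, i, j]
    return gxp[:, pad : pad + h, pad : pad + w]


class Conv2d:
    """k×k convolution; weights initialized N(0, 0.02) as in pix2pix."""

    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_c, self.out_c, self.k, self.stride, self.pad = in_c, out_c, k, stride, pad
        self.W = Param(rng.normal(0.0, 0.02, (out_c, in_c * k * k)).astype(np.float32))
        self.b = Param(np.zeros(out_c, dtype=np.float32))
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, self.k, self.stride, self.pad)
        y = self.W.value @ cols + self.b.value[:, None]
        self._cache = (cols, x.shape, oh, ow)
        return y.reshape(self.out_c, oh, ow)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        g = gy.reshape(self.out_c, -1)
        self.W.grad += g @ cols.T
        self.b.grad += g.sum(axis=1)
        gcols = self.W.value.T @ g
        return _col2im(gcols, x_shape, self.k, self.stride, self.pad, oh, ow)


def _lrelu(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def _lrelu_grad(x, gy, slope=0.2):
    return np.where(x > 0, gy, slope * gy)


def _upsample2(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_grad(gy):
    c, h, w = gy.shape
    return gy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class UNetGenerator:
    """Encoder–decoder with skip connections and a tanh output in [-1, 1].

    ``depth`` stride-2 encoder convolutions halve the plane ``depth`` times
    (input side must be divisible by 2**depth); the decoder mirrors them with
    nearest-neighbour upsampling, concatenating the matching encoder feature
    maps. Channel widths double per level from ``base_channels``.
    """

    def __init__(self, depth: int = 3, base_channels: int = 16, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth, self.base_channels = depth, base_channels
        chans = [base_channels * 2 ** l for l in range(depth)]
        self.enc = []
        prev = 1
        for c in chans:
            self.enc.append(Conv2d(prev, c, k=3, stride=2, pad=1, rng=rng))
            prev = c
        self.dec = []
        for l in range(depth - 1, 0, -1):
            in_c = chans[l] if l == depth - 1 else 2 * chans[l]
            self.dec.append(Conv2d(in_c, chans[l - 1], k=3, stride=1, pad=1, rng=rng))
        final_in = chans[0] if depth == 1 else 2 * chans[0]
        self.final = Conv2d(final_in, 1, k=3, stride=1, pad=1, rng=rng)
        self._cache = None

    @property
    def params(self):
        ps = []
        for layer in [*self.enc, *self.dec, self.final]:
            ps.extend(layer.params)
        return ps

    def named_params(self):
        out = {}
        for i, l in enumerate(self.enc):
            out[f"enc{i}.W"], out[f"enc{i}.b"] = l.W, l.b
        for i, l in enumerate(self.dec):
            out[f"dec{i}.W"], out[f"dec{i}.b"] = l.W, l.b
        out["final.W"], out["final.b"] = self.final.W, self.final.b
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        side = x.shape[1]
        if side % (2 ** self.depth) or x.shape[2] % (2 ** self.depth):
            raise ValueError(f"plane sides {x.shape[1:]} not divisible by 2^{self.depth}")
        x = x.astype(np.float32)
        pre_acts, skips = [], []
        h = x
        for conv in self.enc:
            z = conv.forward(h)
            pre_acts.append(z)
            h = _lrelu(z)
            skips.append(h)
        dec_pre, dec_concat_splits = [], []
        for i, conv in enumerate(self.dec):
            h = _upsample2(h)
            z = conv.forward(h)
            dec_pre.append(z)
            h = _lrelu(z)
            skip = skips[self.depth - 2 - i]
            dec_concat_splits.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
        h = _upsample2(h)
        z_final = self.final.forward(h)
        y = np.tanh(z_final)
        self._cache = (pre_acts, dec_pre, dec_concat_splits, y)
        return y

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients for dLoss/dOutput ``gy``; returns
        dLoss/dInput (unused for the generator but kept for symmetry)."""
        pre_acts, dec_pre, splits, y = self._cache
        if gy.ndim == 2:
            gy = gy[None]
        g = (gy * (1.0 - y * y)).astype(np.float32)  # through tanh
        g = self.final.backward(g)
        g = _upsample2_grad(g)
        skip_grads = [None] * self.depth
        for i in range(len(self.dec) - 1, -1, -1):
            n_dec = splits[i]
            g_dec, g_skip = g[:n_dec], g[n_dec:]
            skip_grads[self.depth - 2 - i] = g_skip
            g_dec = _lrelu_grad(dec_pre[i], g_dec)
            g = self.dec[i].backward(g_dec)
            g = _upsample2_grad(g)
        # g now flows into the deepest encoder activation (skips[-1])
        for l in range(self.depth - 1, -1, -1):
            if skip_grads[l] is not None:
                g = g + skip_grads[l]
            g = _lrelu_grad(pre_acts[l], g)
            g = self.enc[l].backward(g)
        return g


class PatchDiscriminator:
    """Conditional patch discriminator: (MR plane, CT plane) -> 2D score map.

    ``n_levels`` stride-2 convolutions give a score map of side
    input_side / 2**n_levels; at the full 256² scale the default 4 levels
    produce a 16×16 map, at 64² a 4×4 map.
    """

    def __init__(self, n_levels: int = 4, base_channels: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_levels, self.base_channels = n_levels, base_channels
        self.layers = []
        prev = 2
        for l in range(n_levels - 1):
            c = base_channels * 2 ** l
            self.layers.append(Conv2d(prev, c, k=3, stride=2, pad=1, rng=rng))
            prev = c
        self.layers.append(Conv2d(prev, 1, k=3, stride=2, pad=1, rng=rng))
        self._cache = None

    @property
    def params(self):
        ps = []
        for layer in self.layers:
            ps.extend(layer.params)
        return ps

    def named_params(self):
        out = {}
        for i, l in enumerate(self.layers):
            out[f"layer{i}.W"], out[f"layer{i}.b"] = l.W, l.b
        return out

    def forward(self, mr: np.ndarray, ct: np.ndarray) -> np.ndarray:
        if mr.shape[-2:] != ct.shape[-2:]:
            raise ValueError(f"paired planes differ in shape: {mr.shape} vs {ct.shape}")
        x = np.stack([np.asarray(mr, dtype=np.float32).squeeze(),
                      np.asarray(ct, dtype=np.float32).squeeze()])
        pre = []
        h = x
        for conv in self.layers[:-1]:
            z = conv.forward(h)
            pre.append(z)
            h = _lrelu(z)
        z = self.layers[-1].forward(h)
        self._cache = pre
        return z[0]  # (oh, ow) score map

    __call__ = forward

    def backward(self, g_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backprop dLoss/dScoreMap; returns (grad wrt MR plane, grad wrt CT plane)."""
        pre = self._cache
        g = self.layers[-1].backward(np.asarray(g_scores, dtype=np.float32)[None])
        for conv, z in zip(reversed(self.layers[:-1]), reversed(pre)):
            g = _lrelu_grad(z, g)
            g = conv.backward(g)
        return g[0], g[1]


class Adam:
    """Adam with the conditional-GAN momentum defaults (0.5, 0.999)."""

    def __init__(self, params, lr: float, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def save_checkpoint(path: str, generator: UNetGenerator, meta: dict | None = None) -> None:
    """Serialize generator spec + weights (npz with an embedded JSON header)."""
    arrays = {k: p.value for k, p in generator.named_params().items()}
    header = {"depth": generator.depth, "base_channels": generator.base_channels,
              "meta": meta or {}}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str) -> tuple[UNetGenerator, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        g = UNetGenerator(depth=header["depth"], base_channels=header["base_channels"], seed=0)
        for k, p in g.named_params().items():
            p.value = data[k].astype(np.float32)
    return g, header.get("meta", {})
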