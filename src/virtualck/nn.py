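"""Minimal convolutional network stack for the conditional GAN.

Implements exactly the pieces the virtual-staining model needs — strided
convolution, transposed convolution, instance normalization, leaky ReLU /
ReLU / tanh, a U-Net generator with skip connections, a patch-level
discriminator, binary cross-entropy on logits, and Adam — as NumPy arrays
with hand-written backward passes.  Everything operates on single samples
shaped ``(C, H, W)`` in float32 (the training batch size is 1).

Convolutions use im2col/col2im; a transposed convolution is realized as the
exact adjoint of the corresponding strided convolution, so encoder and
decoder geometries mirror each other by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sequential",
    "UNetGenerator",
    "PatchDiscriminator",
    "Adam",
    "bce_with_logits",
]


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, s: int, p: int):
    """Unfold ``(C,H,W)`` into ``(C*k*k, Ho*Wo)`` patch columns."""
    C, H, W = x.shape
    Ho, Wo = _out_size(H, k, s, p), _out_size(W, k, s, p)
    xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
    cols = np.empty((C, k, k, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i : i + s * Ho : s, j : j + s * Wo : s]
    return cols.reshape(C * k * k, Ho * Wo), (Ho, Wo)

def col2im(cols: np.ndarray, C: int, H: int, W: int, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto ``(C,H,W)``."""
    Ho, Wo = _out_size(H, k, s, p), _out_size(W, k, s, p)
    cols = cols.reshape(C, k, k, Ho, Wo)
    xp = np.zeros((C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + s * Ho : s, j : j + s * Wo : s] += cols[:, i, j]
    return xp[:, p : p + H, p : p + W] if p else xp


class Layer:
    def params(self):
        return []

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


class Conv2d(Layer):
    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1, init_std=0.02, bias=True):
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, stride, pad
        self.W = (rng.standard_normal((cout, cin * k * k)) * init_std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None

    def params(self):
        out = [(self.W, self.gW)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out

    def forward(self, x):
        self._in_shape = x.shape
        self._cols, (Ho, Wo) = im2col(x, self.k, self.s, self.p)
        y = self.W @ self._cols
        if self.b is not None:
            y += self.b[:, None]
        return y.reshape(self.cout, Ho, Wo)

    def backward(self, g):
        gf = g.reshape(self.cout, -1).astype(np.float32)
        self.gW += gf @ self._cols.T
        if self.b is not None:
            self.gb += gf.sum(axis=1)
        dcols = self.W.T @ gf
        C, H, W = self._in_shape
        return col2im(dcols, C, H, W, self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; the adjoint of Conv2d's geometry."""

    def __init__(self, cin, cout, rng, k=4, stride=2, pad=1, init_std=0.02):
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, stride, pad
        self.W = (rng.standard_normal((cin, cout * k * k)) * init_std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def out_spatial(self, H, W):
        return ((H - 1) * self.s - 2 * self.p + self.k, (W - 1) * self.s - 2 * self.p + self.k)

    def forward(self, x):
        C, H, W = x.shape
        Ho, Wo = self.out_spatial(H, W)
        self._xf = x.reshape(C, -1)
        cols = self.W.T @ self._xf
        y = col2im(cols, self.cout, Ho, Wo, self.k, self.s, self.p)
        return y + self.b[:, None, None]

    def backward(self, g):
        gcols, (H, W) = im2col(g.astype(np.float32), self.k, self.s, self.p)
        self.gW += self._xf @ gcols.T
        self.gb += g.sum(axis=(1, 2))
        return (self.W @ gcols).reshape(self.cin, H, W)


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial extent, with affine scale."""

    def __init__(self, c, eps=1e-5):
        self.eps = eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma[:, None, None] * self._xhat + self.beta[:, None, None]

    def backward(self, g):
        N = g.shape[1] * g.shape[2]
        self.ggamma += (g * self._xhat).sum(axis=(1, 2))
        self.gbeta += g.sum(axis=(1, 2))
        gx = g * self.gamma[:, None, None]
        mean_g = gx.mean(axis=(1, 2), keepdims=True)
        mean_gx = (gx * self._xhat).mean(axis=(1, 2), keepdims=True)
        return self._istd * (gx - mean_g - self._xhat * mean_gx)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNetGenerator(Layer):
    """Encoder-decoder with symmetric skip connections; tanh output.

    ``depth`` strided 4x4 convolutions halve the spatial size each level;
    the decoder mirrors them with transposed convolutions, concatenating the
    matching encoder feature map at every level but the innermost.  No
    dropout anywhere: inference is deterministic by construction.  Channel
    widths double per level from ``base``, capped at ``8 * base``.
    """

    def __init__(self, rng, in_ch=3, out_ch=3, base=64, depth=8):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        ch = [min(base * 2**i, base * 8) for i in range(depth)]
        self.ch = ch
        self.encs = []
        prev = in_ch
        for i in range(depth):
            block = [Conv2d(prev, ch[i], rng)]
            if i > 0:
                block.append(InstanceNorm(ch[i]))
            block.append(LeakyReLU(0.2))
            self.encs.append(Sequential(block))
            prev = ch[i]
        self.decs = []
        for i in range(depth):
            cin = ch[depth - 1] if i == 0 else 2 * ch[depth - 1 - i]
            if i < depth - 1:
                cout = ch[depth - 2 - i]
                block = [ConvTranspose2d(cin, cout, rng), InstanceNorm(cout), ReLU()]
            else:
                block = [ConvTranspose2d(cin, out_ch, rng), Tanh()]
            self.decs.append(Sequential(block))

    def params(self):
        return [p for m in self.encs + self.decs for p in m.params()]

    def forward(self, x):
        d = self.depth
        size = x.shape[1:]
        if size[0] % 2**d or size[1] % 2**d:
            raise ValueError(f"spatial size {size} not divisible by 2**{d}")
        skips = []
        h = x
        for i, enc in enumerate(self.encs):
            h = enc.forward(h)
            if i < d - 1:
                skips.append(h)
        for i, dec in enumerate(self.decs):
            h = dec.forward(h)
            if i < d - 1:
                h = np.concatenate([h, skips[d - 2 - i]], axis=0)
        return h

    def backward(self, g):
        d = self.depth
        skip_grads = [None] * (d - 1)
        for i in range(d - 1, -1, -1):
            g = self.decs[i].backward(g)
            if i >= 1:
                c_main = self.ch[d - 1 - i]
                skip_grads[d - 1 - i] = g[c_main:]
                g = g[:c_main]
        for i in range(d - 1, -1, -1):
            if i < d - 1:
                g = g + skip_grads[i]
            g = self.encs[i].backward(g)
        return g


class PatchDiscriminator(Sequential):
    """Patch-level real/fake classifier over a concatenated (H&E, CK) input.

    Emits a 2-D grid of logits, one per receptive patch; with the default
    ``n_layers = 3`` the receptive field is the customary ~70x70 pixels.
    """

    def __init__(self, rng, in_ch=6, base=64, n_layers=3):
        layers = [Conv2d(in_ch, base, rng), LeakyReLU(0.2)]
        prev = base
        for n in range(1, n_layers):
            c = min(base * 2**n, base * 8)
            layers += [Conv2d(prev, c, rng), InstanceNorm(c), LeakyReLU(0.2)]
            prev = c
        c = min(base * 2**n_layers, base * 8)
        layers += [Conv2d(prev, c, rng, stride=1), InstanceNorm(c), LeakyReLU(0.2)]
        layers += [Conv2d(c, 1, rng, stride=1)]
        super().__init__(layers)


def bce_with_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy against a constant target; returns (loss, grad)."""
    z = logits.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = ((sig - target) / z.size).astype(np.float32)
    return float(loss), grad


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
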