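"""A compact NumPy U-Net: forward, backprop, and Adam.

Supports 2D and 3D inputs with the classic topology: per resolution level
two 3^d convolutions each followed by ReLU, 2^d max pooling between
levels on the way down, nearest-neighbour upsampling followed by a
convolution ("up-convolution") with skip concatenation on the way up, and
a final 1^d convolution to two classes.  Small enough to train reduced
configurations on a CPU; the layer arithmetic is exact, not approximate.

All activations are channel-first, unbatched arrays (C, *spatial); the
trainer loops over samples and averages gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# einsum programs per spatial ndim: (forward, weight-grad, input-grad)
_EINSUM = {
    2: ("chwij,ocij->ohw", "ohw,chwij->ocij", "ohwij,ocij->chw"),
    3: ("cdhwijk,ocijk->odhw", "odhw,cdhwijk->ocijk", "odhwijk,ocijk->cdhw"),
}


class Conv:
    """Same-padding convolution with cubic kernel (size 3 or 1), stride 1."""

    def __init__(self, cin: int, cout: int, k: int, sd: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k**sd))
        self.W = rng.normal(0.0, std, size=(cout, cin) + (k,) * sd)
        self.b = np.zeros(cout)
        self.k, self.sd = k, sd
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _windows(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        if pad:
            x = np.pad(x, [(0, 0)] + [(pad, pad)] * self.sd)
        return sliding_window_view(
            x, (self.k,) * self.sd, axis=tuple(range(1, self.sd + 1))
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fwd, _, _ = _EINSUM[self.sd]
        y = np.einsum(fwd, self._windows(x), self.W, optimize=True)
        if train:
            self._x = x
        return y + self.b.reshape((-1,) + (1,) * self.sd)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, wgrad, xgrad = _EINSUM[self.sd]
        self.gW += np.einsum(wgrad, dy, self._windows(self._x), optimize=True)
        self.gb += dy.sum(axis=tuple(range(1, self.sd + 1)))
        flip = (slice(None), slice(None)) + (slice(None, None, -1),) * self.sd
        dx = np.einsum(xgrad, self._windows(dy), self.W[flip], optimize=True)
        self._x = None
        return dx


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


class MaxPool:
    """2^d max pooling, stride 2; spatial extents must be even."""

    def __init__(self, sd: int):
        self.sd = sd

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        sd = self.sd
        c, sp = x.shape[0], x.shape[1:]
        half = tuple(s // 2 for s in sp)
        inter = (c,) + tuple(v for s in half for v in (s, 2))
        perm = (0,) + tuple(1 + 2 * i for i in range(sd)) + tuple(
            2 + 2 * i for i in range(sd)
        )
        r = x.reshape(inter).transpose(perm).reshape((c,) + half + (2**sd,))
        idx = r.argmax(-1)
        y = np.take_along_axis(r, idx[..., None], -1)[..., 0]
        if train:
            self._idx, self._in_shape, self._perm = idx, x.shape, perm
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        sd = self.sd
        c = dy.shape[0]
        half = dy.shape[1:]
        g = np.zeros((c,) + half + (2**sd,), dtype=dy.dtype)
        np.put_along_axis(g, self._idx[..., None], dy[..., None], -1)
        g = g.reshape((c,) + half + (2,) * sd)
        return g.transpose(np.argsort(self._perm)).reshape(self._in_shape)


class UpsampleNearest:
    """Nearest-neighbour x2 upsampling."""

    def __init__(self, sd: int):
        self.sd = sd

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = x
        for ax in range(1, self.sd + 1):
            y = np.repeat(y, 2, axis=ax)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, sp = dy.shape[0], dy.shape[1:]
        half = tuple(s // 2 for s in sp)
        inter = (c,) + tuple(v for s in half for v in (s, 2))
        win_axes = tuple(2 + 2 * i for i in range(self.sd))
        return dy.reshape(inter).sum(axis=win_axes)


class NumpyUNet:
    """The assembled network.  ``depth`` counts resolution levels."""

    def __init__(
        self,
        spatial_ndim: int,
        in_channels: int,
        depth: int,
        first_features: int,
        seed: int,
    ):
        if spatial_ndim not in (2, 3):
            raise ValueError("spatial_ndim must be 2 or 3")
        rng = np.random.default_rng(seed)
        sd = spatial_ndim
        self.sd, self.depth = sd, depth
        feats = [first_features * 2**i for i in range(depth)]

        def double_conv(cin, cout):
            return [Conv(cin, cout, 3, sd, rng), ReLU(),
                    Conv(cout, cout, 3, sd, rng), ReLU()]

        self.enc = []
        cin = in_channels
        for f in feats:
            self.enc.append(double_conv(cin, f))
            cin = f
        self.pools = [MaxPool(sd) for _ in range(depth - 1)]
        self.ups, self.upconvs, self.dec = [], [], []
        for i in range(depth - 2, -1, -1):
            self.ups.append(UpsampleNearest(sd))
            self.upconvs.append(Conv(feats[i + 1], feats[i], 3, sd, rng))
            self.dec.append(double_conv(2 * feats[i], feats[i]))
        self.final = Conv(feats[0], 2, 1, sd, rng)

    # -- plumbing ---------------------------------------------------------

    def _conv_layers(self):
        for block in self.enc:
            yield block[0]
            yield block[2]
        yield from self.upconvs
        for block in self.dec:
            yield block[0]
            yield block[2]
        yield self.final

    def params(self):
        out = []
        for layer in self._conv_layers():
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        h = x.astype(float)
        for i, block in enumerate(self.enc):
            for layer in block:
                h = layer.forward(h, train)
            if i < self.depth - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._skip_channels = []
        for up, upconv, block, skip in zip(
            self.ups, self.upconvs, self.dec, reversed(skips)
        ):
            h = upconv.forward(up.forward(h, train), train)
            self._skip_channels.append(skip.shape[0])
            h = np.concatenate([skip, h], axis=0)
            for layer in block:
                h = layer.forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips = []
        for block, upconv, up, csk in zip(
            reversed(self.dec), reversed(self.upconvs), reversed(self.ups),
            reversed(self._skip_channels),
        ):
            for layer in reversed(block):
                d = layer.backward(d)
            dskips.append(d[:csk])
            d = up.backward(upconv.backward(d[csk:]))
        dskips.reverse()  # now ordered bottom-up == reversed encoder order
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                d = self.pools[i].backward(d)
                d = d + dskips[self.depth - 2 - i]
            for layer in reversed(self.enc[i]):
                d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability map via the dual-class softmax."""
        logits = self.forward(x, train=False)
        return softmax2(logits)[1]

    def loss_and_grad(self, x: np.ndarray, target: np.ndarray) -> float:
        """Accumulate BCE (softmax cross-entropy) gradients for one sample."""
        logits = self.forward(x, train=True)
        p = softmax2(logits)
        t = target.astype(float)
        n = t.size
        eps = 1e-12
        loss = -float(
            (t * np.log(p[1] + eps) + (1 - t) * np.log(p[0] + eps)).sum() / n
        )
        dlogits = p.copy()
        dlogits[1] -= t
        dlogits[0] -= 1 - t
        self.backward(dlogits / n)
        return loss

    def loss(self, x: np.ndarray, target: np.ndarray) -> float:
        p = self.predict_proba(x)
        t = target.astype(float)
        eps = 1e-12
        return -float(
            (t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)).mean()
        )


def softmax2(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=0, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=0, keepdims=True)


class Adam:
    """Adam over a fixed list of (param, grad) array pairs."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
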