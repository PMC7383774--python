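"""Differentiable layers with explicit forward/backward passes.

Internally tensors are float32 in NHWC layout (channels last), which lets
stride-1 'same' convolution run as k*k accumulated GEMMs over shifted
views — no im2col patch matrix is ever materialized, and the GEMMs hit
BLAS directly. Each layer caches what its backward pass needs during
``forward(..., train=True)``; inference calls with ``train=False`` skip
caching and use running statistics where applicable. Parameters and their
gradient buffers are exposed through ``named_params()`` as
``(name, param, grad)`` triples for the optimizer and for serialization.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def named_params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 'same' convolution with odd kernel size (shifted-view GEMMs).

    ``weight[u, v]`` is the (c_in, c_out) matrix applied to the input
    shifted by kernel offset (u, v).
    """

    def __init__(self, c_in, c_out, ksize=3, rng=None):
        assert ksize % 2 == 1, "same-padding conv requires odd kernel"
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        rng = rng or np.random.default_rng()
        fan_in = c_in * ksize * ksize
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 (ksize, ksize, c_in, c_out)).astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def named_params(self):
        return [("weight", self.weight, self.dweight),
                ("bias", self.bias, self.dbias)]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        else:
            xp = x
        out = np.empty((n, h, w, self.c_out), dtype=DTYPE)
        out[...] = self.bias
        for u in range(k):
            for v in range(k):
                np.add(out, xp[:, u:u + h, v:v + w, :] @ self.weight[u, v], out=out)
        if train:
            self._xp = xp
        return out

    def backward(self, dy):
        xp = self._xp
        n, h, w, _ = dy.shape
        k, p = self.k, self.k // 2
        self.dbias[...] = dy.sum(axis=(0, 1, 2))
        dyf = dy.reshape(-1, self.c_out)
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                xs = xp[:, u:u + h, v:v + w, :].reshape(-1, self.c_in)
                self.dweight[u, v] = xs.T @ dyf
                dxp[:, u:u + h, v:v + w, :] += (dyf @ self.weight[u, v].T).reshape(n, h, w, self.c_in)
        self._xp = None
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def named_params(self):
        return [("gamma", self.gamma, self.dgamma),
                ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd)
        return (self.gamma * xhat + self.beta).astype(DTYPE, copy=False)

    def backward(self, dy):
        xhat, invstd = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dxhat = dy * self.gamma
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = dy.sum(axis=(0, 1, 2))
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (invstd / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dy):
        idx, (n, h, w, c) = self._cache
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._cache = None
        return np.ascontiguousarray(dx.reshape(n, h, w, c))


class ConvTranspose2x2(Layer):
    """Stride-2, kernel-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, c_in, c_out, rng=None):
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng()
        # weight[k, l] maps input channels to output channels at offset (k, l)
        self.weight = rng.normal(0.0, np.sqrt(2.0 / (c_in * 4)),
                                 (2, 2, c_in, c_out)).astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def named_params(self):
        return [("weight", self.weight, self.dweight),
                ("bias", self.bias, self.dbias)]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        out = np.empty((n, h, 2, w, 2, self.c_out), dtype=DTYPE)
        for k in range(2):
            for l in range(2):
                out[:, :, k, :, l, :] = x @ self.weight[k, l]
        out += self.bias
        if train:
            self._x = x
        return np.ascontiguousarray(out.reshape(n, 2 * h, 2 * w, self.c_out))

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        dyr = dy.reshape(n, h, 2, w, 2, self.c_out)
        self.dbias[...] = dy.sum(axis=(0, 1, 2))
        xf = x.reshape(-1, self.c_in)
        dx = np.zeros_like(x)
        for k in range(2):
            for l in range(2):
                dsub = np.ascontiguousarray(dyr[:, :, k, :, l, :]).reshape(-1, self.c_out)
                self.dweight[k, l] = xf.T @ dsub
                dx += (dsub @ self.weight[k, l].T).reshape(x.shape)
        self._x = None
        return dx


class _Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus an identity (or 1x1 projection) shortcut."""

    def __init__(self, c_in, c_out, rng=None):
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if c_in != c_out:
            self.shortcut = _Sequential(Conv2d(c_in, c_out, 1, rng=rng),
                                        BatchNorm2d(c_out))
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def _children(self):
        kids = {"conv1": self.conv1, "bn1": self.bn1,
                "conv2": self.conv2, "bn2": self.bn2}
        if self.shortcut is not None:
            kids["proj_conv"] = self.shortcut.layers[0]
            kids["proj_bn"] = self.shortcut.layers[1]
        return kids

    def named_params(self):
        out = []
        for cname, child in self._children().items():
            out += [(f"{cname}.{n}", p, g) for n, p, g in child.named_params()]
        return out

    def forward(self, x, train=False):
        main = self.bn1.forward(self.conv1.forward(x, train), train)
        main = self.relu1.forward(main, train)
        main = self.bn2.forward(self.conv2.forward(main, train), train)
        short = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu_out.forward(main + short, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(d)))))
        dshort = d if self.shortcut is None else self.shortcut.backward(d)
        return dmain + dshort
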