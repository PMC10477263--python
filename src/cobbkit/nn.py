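"""Minimal CNN building blocks on numpy with hand-written backprop.

Just enough machinery for the two small networks in this package: 2-D
convolution (im2col), ReLU/sigmoid, 2x2 max-pooling, nearest-neighbour
2x upsampling, global average pooling, a linear layer, the Adam optimiser
and a per-epoch exponential learning-rate schedule.  Arrays are NCHW;
layers take a dtype (the shipped models use float32 — about twice the
matmul throughput of float64 on one CPU core, ample precision for
training).  Batch sizes and feature maps are small, so clarity wins over
micro-optimisation; the deliberate fast path is batched im2col matmuls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Same-padding-by-request convolution, stride 1 or 2, He init."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=None, rng=None, name="conv",
                 dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel // 2) if pad is None else pad
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(dtype)
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=self.w.value.dtype)
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n_, _, ho, wo, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad_out):
        cols, x_shape, xp_shape, ho, wo = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x_shape
        grad_out = np.asarray(grad_out, dtype=self.w.value.dtype)
        g2 = grad_out.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.w.grad += g2.T @ cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.w.value).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros(xp_shape, dtype=self.w.value.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad_out):
        return grad_out * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims required)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad_out):
        n, c, h, w = self._in_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad_out.dtype)
        np.put_along_axis(dflat, self._idx[..., None], grad_out[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad_out):
        n, c, h, w = grad_out.shape
        return grad_out.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Parallel(Layer):
    """Run branches on the same input and concatenate their outputs (NCHW).

    Branches must produce identical spatial sizes; channel counts may
    differ.  Used to fuse a sharp high-resolution branch with a wide
    receptive-field context branch.
    """

    def __init__(self, *branches: "Sequential"):
        self.branches = list(branches)

    def forward(self, x, train=True):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad_out):
        grads = np.split(grad_out, self._splits, axis=1)
        total = None
        for b, g in zip(self.branches, grads):
            gin = b.backward(g)
            total = gin if total is None else total + gin
        return total

    def params(self):
        return [p for b in self.branches for p in b.params()]


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad_out[:, :, None, None], self._in_shape) / (h * w)


class Linear(Layer):
    def __init__(self, d_in, d_out, rng=None, name="linear", dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.w = Param(
            rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_out, d_in)).astype(dtype), f"{name}.w"
        )
        self.b = Param(np.zeros(d_out, dtype=dtype), f"{name}.b")

    def forward(self, x, train=True):
        self._x = np.asarray(x, dtype=self.w.value.dtype)
        return self._x @ self.w.value.T + self.b.value

    def backward(self, grad_out):
        grad_out = np.asarray(grad_out, dtype=self.w.value.dtype)
        self.w.grad += grad_out.T @ self._x
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.w.value

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    # -- checkpointing ------------------------------------------------
    def state_dict(self) -> dict:
        return {f"{i}:{p.name}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays but model has {len(params)} parameters"
            )
        for (key, value), p in zip(sorted(state.items(), key=_state_key), params):
            if value.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key}: {value.shape} vs {p.value.shape}")
            p.value = value.astype(p.value.dtype)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _state_key(item):
    idx = int(item[0].split(":", 1)[0])
    return idx


class Adam:
    """Adam with optional per-epoch exponential learning-rate decay."""

    def __init__(self, params: list[Param], lr=1.25e-4, betas=(0.9, 0.999), eps=1e-8, lr_decay=1.0):
        self.params = params
        self.lr0, self.lr_decay = lr, lr_decay
        self.lr = lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def set_epoch(self, epoch: int) -> None:
        """lr = lr0 * decay**epoch (exponential schedule)."""
        self.lr = self.lr0 * self.lr_decay**epoch

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)
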