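"""Minimal CPU neural-network engine (numpy, float32, manual backprop).

Just enough machinery for small convolutional regressors: Conv2d (dense and
depthwise), Linear, BatchNorm2d, ReLU/SiLU/Sigmoid, 2x2 max pooling, global
average pooling, dropout, sequential containers, squeeze-excitation and
MBConv composite blocks, an Adam optimizer and an L1 loss.

Layout is NHWC (batch, height, width, channels), which keeps the channel
axis contiguous so stride-1 convolutions run as k^2 shifted-slice BLAS
matmuls without an im2col gather.  Every module implements
``forward(x, training)`` and ``backward(grad)`` and caches what it needs.

Determinism: all randomness (init, shuffling, dropout) flows through
``numpy.random.Generator`` objects supplied by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module", "Conv2d", "Linear", "BatchNorm2d", "ReLU", "SiLU", "Sigmoid",
    "MaxPool2x2", "GlobalAvgPool", "Dropout", "Flatten", "Sequential",
    "SqueezeExcite", "MBConv", "Adam", "mae_loss",
]

F32 = np.float32


class Module:
    """Base class: parameter registry plus forward/backward contract."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self):
        """Yield self and every registered sub-module (depth first)."""
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for i, mod in enumerate(self.modules()):
            for name, p in mod.params.items():
                yield f"{i}.{type(mod).__name__}.{name}", mod, name, p

    def n_parameters(self) -> int:
        return sum(p.size for _, _, _, p in self.named_parameters())

    def zero_grad(self):
        for mod in self.modules():
            for name in mod.params:
                mod.grads[name] = np.zeros_like(mod.params[name])

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, mod in enumerate(self.modules()):
            for name, p in mod.params.items():
                out[f"{i}.{name}"] = p.copy()
            for name, b in getattr(mod, "buffers", {}).items():
                out[f"{i}.buf.{name}"] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, mod in enumerate(self.modules()):
            for name in mod.params:
                mod.params[name][...] = state[f"{i}.{name}"]
            for name in getattr(mod, "buffers", {}):
                mod.buffers[name][...] = state[f"{i}.buf.{name}"]

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


# ----------------------------------------------------------------------------
# primitive layers


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d(Module):
    """2D convolution on NHWC tensors; dense or depthwise (groups == cin).

    Dense weights are stored (k, k, cin, cout); depthwise (k, k, cin, mult).
    Stride-1 dense convolution runs as k^2 shifted-slice matmuls; strided
    dense convolution falls back to an im2col gather; depthwise uses einsum.
    """

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None, input_grad=True):
        super().__init__()
        if groups not in (1, in_channels):
            raise ValueError("groups must be 1 or in_channels (depthwise)")
        if groups == in_channels and out_channels % in_channels:
            raise ValueError("depthwise conv needs out_channels % in_channels == 0")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.pad, self.groups = stride, padding, groups
        self.input_grad = input_grad  # first layers can skip the dx pass
        fan_in = (in_channels // groups) * kernel_size**2
        if groups == 1:
            self.params["W"] = _he_init(
                rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in)
        else:
            self.params["W"] = _he_init(
                rng, (kernel_size, kernel_size, in_channels,
                      out_channels // in_channels), fan_in)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=F32)
        self._cache = None

    def _pad(self, x):
        p = self.pad
        if p:
            return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        return x

    def forward(self, x, training=False):
        if x.dtype != F32:
            x = x.astype(F32)
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        oh = (h + 2 * self.pad - k) // s + 1
        ow = (w + 2 * self.pad - k) // s + 1
        xp = self._pad(x)
        W = self.params["W"]
        if self.groups == 1 and s == 1 and c >= 8:
            out = np.zeros((n * oh * ow, self.cout), dtype=F32)
            for i in range(k):
                for j in range(k):
                    sl = xp[:, i : i + oh, j : j + ow, :].reshape(-1, c)
                    out += sl @ W[i, j]
            out = out.reshape(n, oh, ow, self.cout)
            self._cache = ("shift", xp, (n, oh, ow))
        elif self.groups == 1:
            view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            view = view[:, ::s, ::s]  # (n, oh, ow, c, k, k)
            cols = view.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * c)
            Wm = W.reshape(k * k * c, self.cout)
            out = (cols @ Wm).reshape(n, oh, ow, self.cout)
            self._cache = ("im2col", cols, xp.shape, (n, oh, ow))
        else:
            view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            view = view[:, ::s, ::s]  # (n, oh, ow, c, k, k)
            mult = self.cout // self.cin
            out = np.einsum("npqcij,ijcm->npqcm", view, W, optimize=True)
            out = out.reshape(n, oh, ow, self.cout)
            self._cache = ("depthwise", xp, (n, oh, ow))
        if "b" in self.params:
            out += self.params["b"]
        return out

    def backward(self, grad):
        mode = self._cache[0]
        k, s, p = self.k, self.stride, self.pad
        if grad.dtype != F32 or not grad.flags.c_contiguous:
            grad = np.ascontiguousarray(grad, dtype=F32)
        if "b" in self.params:
            self.grads["b"] = self.grads.get("b", 0) + grad.sum(axis=(0, 1, 2))
        W = self.params["W"]
        if mode == "shift":
            _, xp, (n, oh, ow) = self._cache
            gmat = grad.reshape(n * oh * ow, self.cout)
            dW = np.empty_like(W)
            for i in range(k):
                for j in range(k):
                    sl = xp[:, i : i + oh, j : j + ow, :].reshape(-1, self.cin)
                    dW[i, j] = sl.T @ gmat
            self.grads["W"] = self.grads.get("W", 0) + dW
            if not self.input_grad:
                return None
            # dx as a full correlation with flipped weights, same machinery
            q = k - 1 - p
            gpad = np.pad(grad, ((0, 0), (q, q), (q, q), (0, 0))) if q else grad
            h_in, w_in = oh - 1 + k - 2 * p, ow - 1 + k - 2 * p
            dx = np.zeros((n * h_in * w_in, self.cin), dtype=F32)
            for i in range(k):
                for j in range(k):
                    sl = gpad[:, i : i + h_in, j : j + w_in, :].reshape(-1, self.cout)
                    dx += sl @ W[k - 1 - i, k - 1 - j].T
            return dx.reshape(n, h_in, w_in, self.cin)
        if mode == "im2col":
            _, cols, xp_shape, (n, oh, ow) = self._cache
            gmat = grad.reshape(n * oh * ow, self.cout)
            dW = cols.T @ gmat  # (k*k*c, cout)
            self.grads["W"] = self.grads.get("W", 0) + dW.reshape(W.shape)
            if not self.input_grad:
                return None
            dcols = (gmat @ W.reshape(-1, self.cout).T).reshape(
                n, oh, ow, k, k, self.cin)
            dxp = np.zeros(xp_shape, dtype=F32)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + oh * s : s, j : j + ow * s : s, :] += dcols[:, :, :, i, j, :]
            if p:
                dxp = dxp[:, p:-p, p:-p, :]
            return dxp
        # depthwise
        _, xp, (n, oh, ow) = self._cache
        mult = self.cout // self.cin
        gd = grad.reshape(n, oh, ow, self.cin, mult)
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        view = view[:, ::s, ::s]
        dW = np.einsum("npqcm,npqcij->ijcm", gd, view, optimize=True)
        self.grads["W"] = self.grads.get("W", 0) + dW
        dxp = np.zeros(xp.shape, dtype=F32)
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("npqcm,cm->npqc", gd, W[i, j], optimize=True)
                dxp[:, i : i + oh * s : s, j : j + ow * s : s, :] += contrib
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _he_init(rng, (out_features, in_features), in_features)
        self.params["b"] = np.zeros(out_features, dtype=F32)
        self._x = None

    def forward(self, x, training=False):
        self._x = x.astype(F32, copy=False)
        return self._x @ self.params["W"].T + self.params["b"]

    def backward(self, grad):
        grad = grad.astype(F32, copy=False)
        self.grads["W"] = self.grads.get("W", 0) + grad.T @ self._x
        self.grads["b"] = self.grads.get("b", 0) + grad.sum(axis=0)
        return grad @ self.params["W"]


class BatchNorm2d(Module):
    """Batch normalization over (batch, height, width) for NHWC tensors."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.buffers = {
            "running_mean": np.zeros(channels, dtype=F32),
            "running_var": np.ones(channels, dtype=F32),
        }
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, training=False):
        x = x.astype(F32, copy=False)
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.buffers["running_mean"] *= 1 - self.momentum
            self.buffers["running_mean"] += self.momentum * mean
            self.buffers["running_var"] *= 1 - self.momentum
            self.buffers["running_var"] += self.momentum * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad):
        xhat, inv = self._cache
        grad = grad.astype(F32, copy=False)
        self.grads["gamma"] = self.grads.get("gamma", 0) + (grad * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = self.grads.get("beta", 0) + grad.sum(axis=(0, 1, 2))
        g = grad * self.params["gamma"]
        term2 = g.mean(axis=(0, 1, 2))
        term3 = xhat * (g * xhat).mean(axis=(0, 1, 2))
        return (g - term2 - term3) * inv


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class SiLU(Module):
    def forward(self, x, training=False):
        self._x = x
        self._s = 1.0 / (1.0 + np.exp(-x))
        return (x * self._s).astype(F32, copy=False)

    def backward(self, grad):
        s = self._s
        return (grad * (s * (1 + self._x * (1 - s)))).astype(F32, copy=False)


class Sigmoid(Module):
    def forward(self, x, training=False):
        self._s = (1.0 / (1.0 + np.exp(-x))).astype(F32, copy=False)
        return self._s

    def backward(self, grad):
        return grad * self._s * (1 - self._s)


class MaxPool2x2(Module):
    """2x2 max pooling with stride 2 (NHWC; trailing odd row/col dropped)."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, : 2 * h2, : 2 * w2, :]
        blocks = np.ascontiguousarray(
            x.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(n, h2, w2, 4, c)
        self._argmax = blocks.argmax(axis=3)  # first max wins ties
        out = np.take_along_axis(blocks, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._in_shape = (n, h, w, c)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((n, h2, w2, 4, c), dtype=F32)
        np.put_along_axis(dblocks, self._argmax[:, :, :, None, :],
                          grad[:, :, :, None, :].astype(F32, copy=False), axis=3)
        dx = dblocks.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        out = np.zeros((n, h, w, c), dtype=F32)
        out[:, : 2 * h2, : 2 * w2, :] = dx.reshape(n, 2 * h2, 2 * w2, c)
        return out


class GlobalAvgPool(Module):
    """NHWC -> NC global mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2)).astype(F32, copy=False)

    def backward(self, grad):
        n, h, w, c = self._shape
        return (np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)).astype(F32)


class Dropout(Module):
    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Module):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break
        return grad


# ----------------------------------------------------------------------------
# composite blocks (EfficientNet-style)


class SqueezeExcite(Module):
    """Channel gating: GAP -> reduce (SiLU) -> expand (sigmoid) -> scale."""

    def __init__(self, channels, reduced, rng=None):
        super().__init__()
        self.fc1 = Linear(channels, reduced, rng=rng)
        self.act = SiLU()
        self.fc2 = Linear(reduced, channels, rng=rng)
        self.gate = Sigmoid()

    def forward(self, x, training=False):
        self._x = x
        self._shape = x.shape
        s = x.mean(axis=(1, 2))
        s = self.gate.forward(self.fc2.forward(self.act.forward(
            self.fc1.forward(s, training), training), training), training)
        self._s = s
        return x * s[:, None, None, :]

    def backward(self, grad):
        n, h, w, c = self._shape
        dx_direct = grad * self._s[:, None, None, :]
        ds = (grad * self._x).sum(axis=(1, 2))
        ds = self.fc1.backward(self.act.backward(self.fc2.backward(
            self.gate.backward(ds))))
        dx_pool = np.broadcast_to(ds[:, None, None, :], self._shape) / (h * w)
        return (dx_direct + dx_pool).astype(F32, copy=False)


class MBConv(Module):
    """Mobile inverted bottleneck with squeeze-excitation and optional skip."""

    def __init__(self, cin, cout, kernel, stride, expand, se_ratio=0.25, rng=None):
        super().__init__()
        mid = cin * expand
        self.use_expand = expand != 1
        self.use_skip = stride == 1 and cin == cout
        layers = []
        if self.use_expand:
            layers += [Conv2d(cin, mid, 1, bias=False, rng=rng),
                       BatchNorm2d(mid), SiLU()]
        layers += [
            Conv2d(mid, mid, kernel, stride=stride, padding=kernel // 2,
                   groups=mid, bias=False, rng=rng),
            BatchNorm2d(mid), SiLU(),
            SqueezeExcite(mid, max(1, int(cin * se_ratio)), rng=rng),
            Conv2d(mid, cout, 1, bias=False, rng=rng),
            BatchNorm2d(cout),
        ]
        self.body = Sequential(*layers)

    def forward(self, x, training=False):
        out = self.body.forward(x, training=training)
        if self.use_skip:
            out = out + x
        return out

    def backward(self, grad):
        dx = self.body.backward(grad)
        if self.use_skip:
            dx = dx + grad
        return dx


# ----------------------------------------------------------------------------
# optimizer and loss


class Adam:
    def __init__(self, model: Module, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for key, mod, name, p in model.named_parameters():
            self.m[key] = np.zeros_like(p)
            self.v[key] = np.zeros_like(p)

    def step(self):
        self.t += 1
        bias1 = 1 - self.b1**self.t
        bias2 = 1 - self.b2**self.t
        for key, mod, name, p in self.model.named_parameters():
            g = mod.grads.get(name)
            if g is None:
                continue
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            p -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(p.dtype)


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(F32)
    return loss, grad
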