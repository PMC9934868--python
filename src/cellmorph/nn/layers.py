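"""Neural-network building blocks on the autodiff engine.

Layers hold their parameters as named :class:`Tensor` leaves; a
:class:`Module` collects them recursively so optimisers and checkpoints can
address every parameter by a dotted path.  Convolutions are im2col gathers
followed by one matmul; 2x max pooling uses the non-overlapping reshape
trick, so spatial extents must be even wherever a pooling stage applies.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, gather


class Module:
    """Base class: parameter discovery, train/eval free (no stochastic layers)."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for k, v in params.items():
            if v.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = state[k].astype(v.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    """3D convolution, odd kernel, 'same' zero padding, stride 1.

    Input ``(N, C, D, H, W)``; implemented as per-sample im2col gather and a
    single matmul with a ``(k^3*C, C_out)`` weight.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = c_in * kernel ** 3
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        size=(fan_in, c_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def _col_index(self, spatial: tuple[int, int, int]) -> np.ndarray:
        """Flat gather indices (D*H*W, C*k^3) into one padded sample."""
        key = spatial
        if key in self._idx_cache:
            return self._idx_cache[key]
        k, c = self.kernel, self.c_in
        p = k // 2
        D, H, W = spatial
        Dp, Hp, Wp = D + 2 * p, H + 2 * p, W + 2 * p
        oz, oy, ox = np.meshgrid(np.arange(D), np.arange(H), np.arange(W),
                                 indexing="ij")
        base = (oz.ravel()[:, None] * (Hp * Wp) + oy.ravel()[:, None] * Wp
                + ox.ravel()[:, None])  # (DHW, 1) at padded corner offset 0
        kz, ky, kx = np.meshgrid(np.arange(k), np.arange(k), np.arange(k),
                                 indexing="ij")
        koff = (kz.ravel() * (Hp * Wp) + ky.ravel() * Wp + kx.ravel())  # (k^3,)
        chan = np.arange(c) * (Dp * Hp * Wp)
        idx = base + (chan[:, None] + koff[None, :]).reshape(1, -1)
        idx = idx.astype(np.int64)
        self._idx_cache[key] = idx
        return idx

    def __call__(self, x: Tensor) -> Tensor:
        n, c, D, H, W = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p = self.kernel // 2
        xp = x.pad(((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        _, _, Dp, Hp, Wp = xp.shape
        idx = self._col_index((D, H, W))
        per_sample = c * Dp * Hp * Wp
        outs = []
        for i in range(n):
            cols = gather(xp, idx + i * per_sample)       # (DHW, c*k^3)
            o = cols @ self.weight + self.bias            # (DHW, c_out)
            outs.append(o.transpose((1, 0)).reshape(1, self.c_out, D, H, W))
        return outs[0] if n == 1 else concat(outs, axis=0)


class MaxPool3d(Module):
    """Non-overlapping 2x2x2 max pooling."""

    def __call__(self, x: Tensor) -> Tensor:
        n, c, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got "
                             f"{(D, H, W)}")
        y = x.reshape(n, c, D // 2, 2, H // 2, 2, W // 2, 2)
        y = y.transpose((0, 1, 2, 4, 6, 3, 5, 7))
        y = y.reshape(n, c, D // 2, H // 2, W // 2, 8)
        return y.max(axis=5)


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling for (N, C, D, H, W)."""

    def __call__(self, x: Tensor) -> Tensor:
        n, c, D, H, W = x.shape
        flat = np.arange(n * c * D * H * W).reshape(n, c, D, H, W)
        idx = flat.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        return gather(x, idx)


class Adam:
    """Adam with additive L2 weight decay on the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
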