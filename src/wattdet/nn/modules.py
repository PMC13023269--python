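"""Module/parameter containers and the basic layers of the detector."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "Linear", "BatchNorm2d", "MaxPool2d", "Upsample", "SiLU",
    "Profiler", "profiler",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data)
        self.requires_grad = True


class Profiler:
    """Collects multiply-accumulate counts of conv/linear layers per scope."""

    def __init__(self):
        self.active = False
        self.scopes: list[str] = []
        self.macs: dict[str, int] = {}

    def add(self, macs: int):
        if self.active:
            key = self.scopes[-1] if self.scopes else "_root"
            self.macs[key] = self.macs.get(key, 0) + macs

    class _Scope:
        def __init__(self, prof, name):
            self.prof, self.name = prof, name

        def __enter__(self):
            self.prof.scopes.append(self.name)

        def __exit__(self, *exc):
            self.prof.scopes.pop()

    def scope(self, name: str):
        return Profiler._Scope(self, name)

    def start(self):
        self.active = True
        self.macs = {}
        self.scopes = []

    def stop(self) -> dict[str, int]:
        self.active = False
        return self.macs

    @property
    def total(self) -> int:
        return sum(self.macs.values())


profiler = Profiler()


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    # ------------------------------------------------------------ traversal
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mpfx, mod in self.named_modules(prefix):
            for name, p in mod._params.items():
                yield (f"{mpfx}.{name}" if mpfx else name), p

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for mpfx, mod in self.named_modules(prefix):
            for name, b in mod._buffers.items():
                yield (f"{mpfx}.{name}" if mpfx else name), b

    def num_params(self, trainable_only: bool = True) -> int:
        return sum(p.size for p in self.parameters()
                   if p.requires_grad or not trainable_only)

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ---------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {k: p.data for k, p in self.named_parameters()}
        sd.update({k: b for k, b in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict, strict: bool = True):
        own_p = dict(self.named_parameters())
        own_b = {k: (m, n) for k, m, n in
                 ((f"{pfx}.{n}" if pfx else n, mod, n)
                  for pfx, mod in self.named_modules()
                  for n in mod._buffers)}
        missing = [k for k in list(own_p) + list(own_b) if k not in sd]
        unexpected, mismatched = [], []
        for k, v in sd.items():
            if k in own_p:
                if own_p[k].shape != v.shape:
                    mismatched.append(k)
                else:
                    own_p[k].data = np.asarray(v, dtype=np.float32).copy()
            elif k in own_b:
                mod, n = own_b[k]
                mod.register_buffer(n, np.asarray(v, dtype=np.float32).copy())
            else:
                unexpected.append(k)
        if strict and (missing or unexpected or mismatched):
            raise KeyError(f"state mismatch: missing={missing[:5]} "
                           f"unexpected={unexpected[:5]} shape={mismatched[:5]}")
        return {"missing": missing, "unexpected": unexpected,
                "mismatched": mismatched}

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / fan_in)  # uniform He-style init, matches conv default
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_init_rng: list[np.random.Generator] = [np.random.default_rng(0)]


def set_init_rng(seed: int):
    _init_rng[0] = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, s=1, p=0, groups=1, bias=True):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.p, self.groups = c1, c2, k, s, p, groups
        fan_in = (c1 // groups) * k * k
        rng = _init_rng[0]
        self.weight = Parameter(_kaiming(rng, (c2, c1 // groups, k, k), fan_in))
        self.bias = Parameter(_kaiming(rng, (c2,), fan_in)) if bias else None

    def forward(self, x):
        out = F.conv2d(x, self.weight, self.bias, self.s, self.p, self.groups)
        profiler.add(F.conv2d_macs(x.shape[0], self.c1, self.c2, self.k,
                                   out.shape[2], out.shape[3], self.groups))
        return out


class Linear(Module):
    def __init__(self, c1, c2, bias=True):
        super().__init__()
        rng = _init_rng[0]
        self.weight = Parameter(_kaiming(rng, (c2, c1), c1))
        self.bias = Parameter(_kaiming(rng, (c2,), c1)) if bias else None

    def forward(self, x):
        out = x.matmul(self.weight.transpose(1, 0))
        if self.bias is not None:
            out = out + self.bias
        profiler.add(int(np.prod(x.shape[:-1])) * self.weight.shape[0]
                     * self.weight.shape[1])
        return out


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        # unfused normalization: two multiply-adds per element
        profiler.add(2 * x.data.size)
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mu - rm)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * n / max(n - 1, 1)
            rv += self.momentum * (unbiased - rv)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]

        mu_t, var_t = mu.reshape(1, -1, 1, 1), var.reshape(1, -1, 1, 1)
        inv = 1.0 / np.sqrt(var_t + self.eps)
        xhat_data = (x.data - mu_t) * inv
        w = self.weight.data.reshape(1, -1, 1, 1)
        out_data = xhat_data * w + self.bias.data.reshape(1, -1, 1, 1)
        training = self.training

        def bw(out_t):
            def fn():
                go = out_t.grad
                if self.weight.requires_grad:
                    self.weight._accum((go * xhat_data).sum(axis=(0, 2, 3)))
                if self.bias.requires_grad:
                    self.bias._accum(go.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    if training:
                        n = go.shape[0] * go.shape[2] * go.shape[3]
                        gxh = go * w
                        m1 = gxh.mean(axis=(0, 2, 3), keepdims=True)
                        m2 = (gxh * xhat_data).mean(axis=(0, 2, 3), keepdims=True)
                        x._accum(inv * (gxh - m1 - xhat_data * m2))
                    else:
                        x._accum(go * w * inv)
            return fn

        return Tensor._make(out_data, (x, self.weight, self.bias), bw)


class MaxPool2d(Module):
    def __init__(self, k, s=1, p=0):
        super().__init__()
        self.k, self.s, self.p = k, s, p

    def forward(self, x):
        return F.max_pool2d(x, self.k, self.s, self.p)


class Upsample(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return F.upsample_nearest2x(x)
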