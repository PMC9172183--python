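"""2D residual U-Net for lung segmentation, implemented in numpy.

The architecture follows the winning configuration of the segmentation
recipe: an input stem, three downsampling layers, one bridge layer and four
upsampling layers, where each layer's block is two cycles of (batch
normalization, 3x3 convolution, leaky ReLU) wrapped in a residual skip. The
fourth upsampling layer is a resolution-preserving refinement block (the
encoder halves the grid three times, so only three spatial upsamplings are
needed to return to full resolution). The head is a 1x1 convolution with no
output nonlinearity; its output is interpreted as logits, so thresholding
the probability map at 0.5 is exactly ``logits > 0``.

Everything — forward passes, gradients, the Adam optimizer — is written on
top of numpy's BLAS-backed matmul via im2col, in float32 by default (float64
is available for gradient checking). The network is
fully convolutional: it trains on small crops and runs inference on any grid
whose sides are multiples of the total downsampling factor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: default compute dtype; float32 keeps desk-scale CPU training fast
DTYPE = np.float32

__all__ = ["SegModelConfig", "ResidualUNet"]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture and decision parameters of the segmentation network.

    ``down_layers``/``bridge_layers``/``up_layers`` default to the winning
    configuration (3/1/4); ``batch_size`` defaults to the faithful 64, with
    smaller values used for desk-scale training. ``threshold`` converts the
    probability map into a mask; ``loss_eps`` is the Soft-Jaccard smoothing
    term.
    """

    down_layers: int = 3
    bridge_layers: int = 1
    up_layers: int = 4
    block_cycles: int = 2
    base_channels: int = 8
    batch_size: int = 64
    threshold: float = 0.5
    loss_eps: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.up_layers < self.down_layers:
            raise ValueError("need at least one upsampling layer per downsampling")

    @property
    def downsampling_factor(self) -> int:
        return 2 ** self.down_layers


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------

def _conv_same(x, wmat, bias, k):
    """Stride-1 same-padding correlation. x: (N,C,H,W); wmat: (Cout, C*k*k)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))          # N,C,H,W,k,k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    cols = cols.reshape(n, h * w, c * k * k)
    out = cols @ wmat.T
    if bias is not None:
        out += bias
    return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2), cols


class _Conv:
    def __init__(self, cin, cout, k, rng):
        fan_in = cin * k * k
        # He initialization (gain for leaky ReLU alpha=0.01)
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin * k * k)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.k, self.cin, self.cout = k, cin, cout
        self._cols = None
        self._xshape = None

    def forward(self, x, train):
        out, cols = _conv_same(x, self.w, self.b, self.k)
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out

    def backward(self, g):
        n, cout, h, w = g.shape
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.gw = gmat.T @ self._cols.reshape(-1, self._cols.shape[-1])
        self.gb = gmat.sum(axis=0)
        # dx = correlation of g with the flipped, transposed kernel
        wback = (self.w.reshape(self.cout, self.cin, self.k, self.k)
                 .transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
                 .reshape(self.cin, self.cout * self.k * self.k))
        wback = np.ascontiguousarray(wback)
        dx, _ = _conv_same(g, wback, None, self.k)
        self._cols = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, g):
        xhat, invstd = self._cache
        m = g.shape[0] * g.shape[2] * g.shape[3]
        self.ggamma = (g * xhat).sum(axis=(0, 2, 3))
        self.gbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * self.gamma[None, :, None, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        dx *= invstd[None, :, None, None]
        self._cache = None
        return dx

    def params(self):
        return [("gamma", self), ("beta", self)]


class _LeakyReLU:
    def __init__(self, alpha=0.01):
        self.alpha = alpha

    def forward(self, x, train):
        if train:
            self._neg = x < 0
        return np.where(x < 0, self.alpha * x, x)

    def backward(self, g):
        g = np.where(self._neg, self.alpha * g, g)
        self._neg = None
        return g

    def params(self):
        return []


class _ResBlock:
    """``block_cycles`` cycles of (BN, conv3x3, leaky ReLU) plus a residual
    skip (1x1 convolution when the channel count changes)."""

    def __init__(self, cin, cout, cycles, rng):
        self.layers = []
        c = cin
        for _ in range(cycles):
            self.layers += [_BatchNorm(c), _Conv(c, cout, 3, rng), _LeakyReLU()]
            c = cout
        self.skip = _Conv(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x, train):
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        res = self.skip.forward(x, train) if self.skip is not None else x
        return out + res

    def backward(self, g):
        dres = self.skip.backward(g) if self.skip is not None else g
        dx = g
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        return dx + dres

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        if self.skip is not None:
            out += self.skip.params()
        return out


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(g):
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_back(g):
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class ResidualUNet:
    """Residual U-Net emitting one-channel logits at input resolution."""

    def __init__(self, config: SegModelConfig | None = None, seed: int = 0,
                 dtype=DTYPE):
        self.config = config or SegModelConfig()
        self.dtype = np.dtype(dtype)
        cfg = self.config
        rng = np.random.default_rng(seed)
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.down_layers + 1)]

        self.stem = _Conv(1, ch[0], 3, rng)
        self.down = [
            _ResBlock(ch[i], ch[i + 1], cfg.block_cycles, rng)
            for i in range(cfg.down_layers)
        ]
        self.bridge = [
            _ResBlock(ch[-1], ch[-1], cfg.block_cycles, rng)
            for _ in range(cfg.bridge_layers)
        ]
        self.up_conv = [
            _Conv(ch[i + 1], ch[i], 3, rng)
            for i in reversed(range(cfg.down_layers))
        ]
        self.up_block = [
            _ResBlock(ch[i], ch[i], cfg.block_cycles, rng)
            for i in reversed(range(cfg.down_layers))
        ]
        self.refine = [
            _ResBlock(ch[0], ch[0], cfg.block_cycles, rng)
            for _ in range(cfg.up_layers - cfg.down_layers)
        ]
        self.head = _Conv(ch[0], 1, 1, rng)
        self.trained = False
        if self.dtype != np.dtype(DTYPE):
            for name, owner in self.parameters():
                setattr(owner, name, getattr(owner, name).astype(self.dtype))
            for mod in self._modules():
                for lyr in getattr(mod, "layers", []):
                    if isinstance(lyr, _BatchNorm):
                        lyr.running_mean = lyr.running_mean.astype(self.dtype)
                        lyr.running_var = lyr.running_var.astype(self.dtype)

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        return ([self.stem] + self.down + self.bridge
                + self.up_conv + self.up_block + self.refine + [self.head])

    def parameters(self):
        out = []
        for mod in self._modules():
            out += mod.params()
        return out

    def forward(self, x, train=False):
        """x: (N, H, W) standardized slices -> (N, H, W) logits."""
        x = np.asarray(x, dtype=self.dtype)[:, None, :, :]
        f = self.config.downsampling_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(f"input sides must be multiples of {f}")
        h = self.stem.forward(x, train)
        skips = []
        for blk in self.down:
            skips.append(h)
            h = blk.forward(_avgpool2(h), train)
        for blk in self.bridge:
            h = blk.forward(h, train)
        for conv, blk, skip in zip(self.up_conv, self.up_block, reversed(skips)):
            h = conv.forward(_upsample2(h), train)
            h = blk.forward(h + skip, train)
        for blk in self.refine:
            h = blk.forward(h, train)
        logits = self.head.forward(h, train)
        return logits[:, 0]

    def backward(self, dlogits):
        g = self.head.backward(np.asarray(dlogits, dtype=self.dtype)[:, None])
        for blk in reversed(self.refine):
            g = blk.backward(g)
        dskips = []
        for conv, blk in zip(reversed(self.up_conv), reversed(self.up_block)):
            g = blk.backward(g)
            dskips.append(g)
            g = _upsample2_back(conv.backward(g))
        for blk in reversed(self.bridge):
            g = blk.backward(g)
        for blk, dskip in zip(reversed(self.down), reversed(dskips)):
            g = _avgpool2_back(blk.backward(g))
            g = g + dskip
        return self.stem.backward(g)[:, 0]

    # -- inference ---------------------------------------------------------
    def predict_proba(self, x):
        """Sigmoid probability map for standardized slices (N, H, W)."""
        z = np.clip(self.forward(x, train=False), -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(-z))

    def predict_mask(self, x):
        return self.predict_proba(x) >= self.config.threshold

    # -- serialization -----------------------------------------------------
    def state_arrays(self):
        arrays = {}
        for i, (name, owner) in enumerate(self.parameters()):
            arrays[f"p{i}_{name}"] = getattr(owner, name)
        bn = [m for mod in self._modules() for m in getattr(mod, "layers", [])
              if isinstance(m, _BatchNorm)]
        bn += [m for mod in self._modules() if isinstance(mod, _BatchNorm)]
        for i, m in enumerate(bn):
            arrays[f"bn{i}_mean"] = m.running_mean
            arrays[f"bn{i}_var"] = m.running_var
        return arrays

    def save(self, path):
        arrays = self.state_arrays()
        arrays["_config_json"] = np.frombuffer(
            json.dumps(asdict(self.config) | {"trained": self.trained}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ResidualUNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_config_json"].tobytes()).decode())
            trained = meta.pop("trained")
            model = cls(SegModelConfig(**meta))
            for i, (name, owner) in enumerate(model.parameters()):
                setattr(owner, name, data[f"p{i}_{name}"].copy())
            bn = [m for mod in model._modules()
                  for m in getattr(mod, "layers", []) if isinstance(m, _BatchNorm)]
            for i, m in enumerate(bn):
                m.running_mean = data[f"bn{i}_mean"].copy()
                m.running_var = data[f"bn{i}_var"].copy()
        model.trained = trained
        return model


class Adam:
    """Adam optimizer over the network's (name, owner) parameter handles."""

    def __init__(self, model: ResidualUNet, lr=2e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.handles = model.parameters()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for n, o in self.handles]
        self.v = [np.zeros_like(getattr(o, n)) for n, o in self.handles]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, owner) in enumerate(self.handles):
            g = getattr(owner, "g" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p = getattr(owner, name)
            setattr(owner, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
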