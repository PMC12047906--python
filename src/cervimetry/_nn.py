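"""Minimal 3D convolutional network engine on numpy.

Implements exactly the pieces the cervix parcellation network needs —
same-padded 3^3 convolutions (im2col/GEMM), batch normalisation at batch
size 1 (spatial statistics), ReLU, dropout, 2x max pooling,
nearest-neighbour upsampling, channel concatenation, a softmax Dice +
cross-entropy loss and the AdamW optimiser with decoupled weight decay —
with hand-written backward passes.  Single-volume batches only; tensors
are channel-first ``(C, D, H, W)`` float32.
"""

from __future__ import annotations

import numpy as np

try:  # fused numba kernels; the GEMM path below is the fallback
    from . import _conv_numba
except ImportError:  # pragma: no cover - numba is normally present
    _conv_numba = None

# ---------------------------------------------------------------------------
# conv primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (C*k^3, D*H*W) patch matrix, same padding (k odd).

    Channel-major layout so each of the k^3 taps is one plain strided-slice
    copy of the padded array (memory-bandwidth bound, no gather), and the
    convolution itself is a single GEMM against the (c_out, c_in*k^3)
    weight matrix.
    """
    c, d, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.empty((c, k * k * k, d, h, w), dtype=np.float32)
    o = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out[:, o] = xp[:, i:i + d, j:j + h, l:l + w]
                o += 1
    return out.reshape(c * k**3, d * h * w)


class Conv3d:
    """Same-padded 3D convolution, odd kernel, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        self.w = (rng.standard_normal((c_out, c_in, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        c_out = self.w.shape[0]
        shape = (c_out,) + x.shape[1:]
        if self.k != 1 and _conv_numba is not None:
            return _conv_numba.conv3d_forward(x, self.w, self.b)
        wmat = self.w.reshape(c_out, -1)
        if self.k == 1:
            y = wmat @ x.reshape(x.shape[0], -1)
        else:
            y = wmat @ _im2col(x, self.k)
        y += self.b[:, None]
        return y.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward before forward(train=True)"
        c_out = self.w.shape[0]
        dymat = dy.reshape(c_out, -1)
        self.db += dymat.sum(axis=1)
        if self.k == 1:
            self.dw += (dymat @ x.reshape(x.shape[0], -1).T).reshape(self.w.shape)
            dx = self.w.reshape(c_out, -1).T @ dymat
            self._x = None
            return dx.reshape(x.shape)
        if _conv_numba is not None:
            _conv_numba.conv3d_backward_weights(x, dy, self.dw)
            dx = _conv_numba.conv3d_backward_input(dy, self.w, x.shape)
            self._x = None
            return dx
        cols = _im2col(x, self.k)
        self.dw += (dymat @ cols.T).reshape(self.w.shape)
        # dx: correlate dy with the spatially flipped, in/out-swapped kernel
        wt = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)  # (c_in, c_out, k,k,k)
        dx = wt.reshape(wt.shape[0], -1) @ _im2col(dy, self.k)
        self._x = None
        return dx.reshape(x.shape)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm3d:
    """Batch normalisation at batch size 1: per-channel spatial statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros(c, dtype=np.float32)
        self.dbeta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[0]
        xr = x.reshape(c, -1)
        if train:
            mean = xr.mean(axis=1)
            var = xr.var(axis=1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xr - mean[:, None]) * inv[:, None]
        if train:
            self._cache = (xhat, inv)
        y = self.gamma[:, None] * xhat + self.beta[:, None]
        return y.reshape(x.shape).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        c = dy.shape[0]
        dyr = dy.reshape(c, -1)
        n = dyr.shape[1]
        self.dgamma += (dyr * xhat).sum(axis=1)
        self.dbeta += dyr.sum(axis=1)
        g = self.gamma[:, None] * dyr
        dx = inv[:, None] / n * (
            n * g - g.sum(axis=1, keepdims=True) - xhat * (g * xhat).sum(axis=1, keepdims=True)
        )
        self._cache = None
        return dx.reshape(dy.shape).astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class Dropout:
    def __init__(self, p: float):
        self.p = p

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2x2 max pooling; returns (pooled, argmax-mask for backward)."""
    c, d, h, w = x.shape
    xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(2, 4, 6))
    mask = xr == y[:, :, None, :, None, :, None]
    # break ties: normalise so gradient mass is conserved
    counts = mask.sum(axis=(2, 4, 6), keepdims=True)
    return y, (mask / counts).astype(np.float32)


def maxpool2_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    dx = mask * dy[:, :, None, :, None, :, None]
    return dx.reshape(c, d * 2, h * 2, w * 2)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


# ---------------------------------------------------------------------------
# loss


def softmax(z: np.ndarray) -> np.ndarray:
    zm = z - z.max(axis=0, keepdims=True)
    e = np.exp(zm, dtype=np.float32)
    return e / e.sum(axis=0, keepdims=True)


def dice_ce_loss(
    logits: np.ndarray,
    target: np.ndarray,
    n_classes: int,
    dice_weight: float = 1.0,
    ce_weight: float = 1.0,
    eps: float = 1e-5,
) -> tuple[float, np.ndarray, dict]:
    """Combined soft-Dice + cross-entropy loss and its gradient w.r.t. logits.

    ``logits``: (C, D, H, W); ``target``: (D, H, W) integer codes.
    Returns (loss, dlogits, parts) where parts holds the two terms and the
    per-class soft Dice scores.
    """
    c = n_classes
    zr = logits.reshape(c, -1)
    t = target.reshape(-1)
    n = t.size
    p = softmax(zr)
    onehot = np.zeros_like(p)
    onehot[t, np.arange(n)] = 1.0

    logp = np.log(np.clip(p[t, np.arange(n)], 1e-12, None))
    ce = -float(logp.mean())

    inter = (p * onehot).sum(axis=1)
    sums = p.sum(axis=1) + onehot.sum(axis=1)
    dice_scores = (2.0 * inter + eps) / (sums + eps)
    dice_loss = float(1.0 - dice_scores.mean())

    # gradients w.r.t. p
    g = np.zeros_like(p)
    if ce_weight:
        # d(CE)/dz has the closed form (p - onehot)/n; fold in later directly
        pass
    if dice_weight:
        s2 = (sums + eps)[:, None]
        g += -dice_weight / c * (2.0 * onehot * s2 - (2.0 * inter + eps)[:, None]) / s2**2
    # chain softmax: dz_c = p_c * (g_c - sum_k g_k p_k)
    dz = p * (g - (g * p).sum(axis=0, keepdims=True))
    if ce_weight:
        dz += ce_weight * (p - onehot) / n
    loss = ce_weight * ce + dice_weight * dice_loss
    parts = {"ce": ce, "dice_loss": dice_loss, "dice_per_class": dice_scores}
    return float(loss), dz.reshape(logits.shape).astype(np.float32), parts


# ---------------------------------------------------------------------------
# optimiser


class AdamW:
    """AdamW with decoupled weight decay and an external LR schedule."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs; updated in place
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr * ((m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.wd * p)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


# ---------------------------------------------------------------------------
# the UNet


class UNet3D:
    """Encoder-decoder 3D segmentation network.

    ``n_blocks`` resolution levels with the given output channels; each
    level applies ``convs_per_block`` conv+BN+ReLU units; 2x max-pool
    between encoder levels; the decoder upsamples (nearest), convolves to
    the skip width, concatenates the skip and convolves again; dropout sits
    after the bottleneck; a 1^3 convolution maps to class logits.
    """

    def __init__(
        self,
        in_channels: int = 1,
        n_classes: int = 6,
        channels: tuple[int, ...] = (32, 64, 128, 256, 512),
        kernel: int = 3,
        convs_per_block: int = 2,
        dropout: float = 0.5,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.n_classes = n_classes
        self.kernel = kernel
        self.convs_per_block = convs_per_block
        self.depth = len(channels)
        self.enc: list[list] = []
        c_prev = in_channels
        for c in channels:
            block = []
            for j in range(convs_per_block):
                block += [Conv3d(c_prev if j == 0 else c, c, kernel, rng), BatchNorm3d(c), ReLU()]
            self.enc.append(block)
            c_prev = c
        self.drop = Dropout(dropout)
        self.dec: list[dict] = []
        for d in range(self.depth - 2, -1, -1):
            up = [Conv3d(channels[d + 1], channels[d], kernel, rng), BatchNorm3d(channels[d]), ReLU()]
            merge = []
            for j in range(convs_per_block):
                cin = channels[d] * 2 if j == 0 else channels[d]
                merge += [Conv3d(cin, channels[d], kernel, rng), BatchNorm3d(channels[d]), ReLU()]
            self.dec.append({"level": d, "up": up, "merge": merge})
        self.head = Conv3d(channels[0], n_classes, 1, rng)

    # -- execution ----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """x: (1, D, H, W) float32 -> logits (n_classes, D, H, W)."""
        self._pool_masks = []
        skips = []
        h = x
        for d, block in enumerate(self.enc):
            for layer in block:
                h = layer.forward(h, train)
            if d < self.depth - 1:
                skips.append(h)
                h, mask = maxpool2(h)
                self._pool_masks.append(mask if train else None)
        h = self.drop.forward(h, train, rng)
        self._skip_channels = [s.shape[0] for s in skips]
        for stage in self.dec:
            h = upsample2(h)
            for layer in stage["up"]:
                h = layer.forward(h, train)
            skip = skips.pop()
            h = np.concatenate([skip, h], axis=0)
            for layer in stage["merge"]:
                h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads: list[np.ndarray] = []
        for stage in reversed(self.dec):
            for layer in reversed(stage["merge"]):
                g = layer.backward(g)
            c_skip = self.channels[stage["level"]]
            skip_grads.append(g[:c_skip])
            g = g[c_skip:]
            for layer in reversed(stage["up"]):
                g = layer.backward(g)
            g = upsample2_backward(g)
        g = self.drop.backward(g)
        for d in range(self.depth - 1, -1, -1):
            if d < self.depth - 1:
                g = maxpool2_backward(g, self._pool_masks[d])
                g = g + skip_grads[d]
            for layer in reversed(self.enc[d]):
                g = layer.backward(g)
        self._pool_masks = []

    # -- parameters ---------------------------------------------------------

    def layers(self):
        for block in self.enc:
            yield from block
        yield self.drop
        for stage in self.dec:
            yield from stage["up"]
            yield from stage["merge"]
        yield self.head

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for attr in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, attr):
                    state[f"layer{i:03d}.{attr}"] = getattr(layer, attr)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for attr in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                key = f"layer{i:03d}.{attr}"
                if hasattr(layer, attr):
                    getattr(layer, attr)[...] = state[key]
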