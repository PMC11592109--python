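"""The multitask U-Net: encoder, connection block, decoder, two heads.

Structure for ``depth = D`` and ``base_filters = f``:

- encoder: D double-conv blocks with f * 2^d filters, each followed by 2x2
  max pooling;
- connection block: 1x1 convolution to f * 2^D filters with instance
  normalisation and ReLU, adapting encoder features for the decoder;
- decoder: D stages of nearest-neighbour upsampling, concatenation with
  the matching encoder skip, and a double-conv block back to f * 2^d;
- segmentation head: 1x1 convolution to one logit per pixel;
- counting head: global average pooling of the connection-block output,
  a hidden dense layer and a softplus output predicting log1p(count),
  which keeps predicted counts non-negative by construction.

``residual=True`` adds an identity (or 1x1-projected) shortcut around each
double-conv block.
"""

from __future__ import annotations

import copy

import numpy as np

from .config import ArchConfig
from .layers import Conv2D, Dense, InstanceNorm, MaxPool2, ReLU, Softplus, UpNearest2

__all__ = ["MultitaskUNet", "build_model"]


class DoubleConv:
    """conv-relu-conv(-shortcut)-relu."""

    def __init__(self, cin, cout, residual, rng):
        self.conv1 = Conv2D(cin, cout, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(cout, cout, 3, rng)
        self.relu2 = ReLU()
        self.residual = residual
        self.proj = Conv2D(cin, cout, 1, rng) if residual and cin != cout else None

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.conv2.forward(h)
        if self.residual:
            h = h + (self.proj.forward(x) if self.proj is not None else x)
        return self.relu2.forward(h)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        if self.residual:
            dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx


class MultitaskUNet:
    """Two-output network: per-pixel foreground logits and a count estimate."""

    def __init__(self, arch: ArchConfig, seed: int = 0):
        self.arch = arch
        self.seed = seed
        rng = np.random.default_rng(seed)
        f, depth = arch.base_filters, arch.depth
        self.enc = []
        cin = 1
        for d in range(depth):
            self.enc.append(DoubleConv(cin, f * 2**d, arch.residual, rng))
            cin = f * 2**d
        self.pools = [MaxPool2() for _ in range(depth)]
        cbot = f * 2**depth
        self.conn = Conv2D(cin, cbot, 1, rng)
        self.conn_norm = InstanceNorm()
        self.conn_relu = ReLU()
        self.ups = []
        self.dec = []
        c_up = cbot
        for d in reversed(range(depth)):
            c_skip = f * 2**d
            self.ups.append(UpNearest2())
            self.dec.append(DoubleConv(c_up + c_skip, c_skip, arch.residual, rng))
            c_up = c_skip
        self.seg_head = Conv2D(c_up, 1, 1, rng)
        self.fc1 = Dense(cbot, arch.regression_hidden, rng)
        self.fc_relu = ReLU()
        self.fc2 = Dense(arch.regression_hidden, 1, rng)
        self.softplus = Softplus()

    # -- parameters -----------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc + self.dec:
            out += blk.params()
        out += self.conn.params() + self.seg_head.params()
        out += self.fc1.params() + self.fc2.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        for (p, _), w in zip(self.params(), weights):
            p[...] = w

    def clone(self) -> "MultitaskUNet":
        other = MultitaskUNet(self.arch, self.seed)
        other.set_weights(self.get_weights())
        return other

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray):
        """x: (N, H, W) in [0, 1].  Returns (logits (N,H,W), y (N,) with
        y = softplus output approximating log1p(count))."""
        h = np.asarray(x, dtype=np.float32)[..., None]
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.conn_relu.forward(self.conn_norm.forward(self.conn.forward(h)))
        self._bshape = h.shape
        gap = h.mean(axis=(1, 2))
        u = self.fc2.forward(self.fc_relu.forward(self.fc1.forward(gap)))
        y = self.softplus.forward(u)[:, 0]
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=3)
            blk._c_up = h.shape[3] - skip.shape[3]
            h = blk.forward(h)
        logits = self.seg_head.forward(h)[:, :, :, 0]
        return logits, y

    def backward(self, dlogits: np.ndarray, dy: np.ndarray):
        """Accumulate parameter gradients for upstream gradients of the two
        outputs (shapes (N,H,W) and (N,))."""
        dh = self.seg_head.backward(dlogits[..., None].astype(np.float32))
        dskips = [None] * len(self.enc)
        depth = len(self.enc)
        for i in range(depth - 1, -1, -1):  # reverse decoder order
            blk, up = self.dec[i], self.ups[i]
            d = blk.backward(dh)
            c_up = blk._c_up
            d_up, d_skip = d[..., :c_up], d[..., c_up:]
            skip_idx = depth - 1 - i
            dskips[skip_idx] = d_skip
            dh = up.backward(d_up)
        # count head joins at the connection block output
        du = self.softplus.backward(dy[:, None].astype(np.float32))
        dgap = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(du)))
        n, hb, wb, cb = self._bshape
        dh = dh + dgap[:, None, None, :] / (hb * wb)
        dh = self.conn.backward(self.conn_norm.backward(self.conn_relu.backward(dh)))
        for i in range(depth - 1, -1, -1):
            d = self.pools[i].backward(dh) + dskips[i]
            dh = self.enc[i].backward(d)
        return dh[..., 0]


def build_model(arch: ArchConfig | None = None, seed: int = 0) -> MultitaskUNet:
    """Instantiate a seeded model; identical (arch, seed) give identical
    initial parameters."""
    return MultitaskUNet(arch or ArchConfig(), seed)
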