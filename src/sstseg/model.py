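"""Encoder-decoder segmentation backbone and instance-probability assembly.

The backbone contract: input = one cell's conditioning channel (its binary
nucleus mask) concatenated with the shared expression patch, shape
(n_cells, n_genes + 1, h, w) with the patch's cells stacked along the batch
axis; output = 2 logit channels (background, foreground) at input resolution.
The reference backbone is a small 3-level encoder-decoder with skip
connections, implemented in NumPy with explicit backpropagation and He weight
initialisation.  Alternative backbones register via ``register_backbone``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class PatchBatch:
    expression: np.ndarray        # h x w x n_genes counts
    per_cell_nucleus: np.ndarray  # n_cells x h x w binary
    cell_ids: list                # labels, order matches the batch axis

    def __post_init__(self):
        if len(self.cell_ids) != self.per_cell_nucleus.shape[0]:
            raise ValueError("cell_ids length must match nucleus stack")
        if len(self.cell_ids) < 1:
            raise ValueError("a trainable/predictable patch needs >= 1 cell")

    def network_input(self) -> np.ndarray:
        """(n_cells, n_genes + 1, h, w): raw counts + per-cell nucleus channel."""
        genes = self.expression.transpose(2, 0, 1).astype(np.float64)
        M = len(self.cell_ids)
        shared = np.broadcast_to(genes, (M,) + genes.shape)
        nuc = self.per_cell_nucleus[:, None].astype(np.float64)
        return np.concatenate([shared, nuc], axis=1)


@dataclass
class InstanceProbabilities:
    foreground: np.ndarray  # n_cells x h x w, in [0, 1]
    background: np.ndarray  # 1 - foreground

    def __post_init__(self):
        if not np.allclose(self.foreground + self.background, 1.0, atol=1e-6):
            raise ValueError("foreground + background must equal 1 per pixel")


class ContractViolation(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# layers


class Conv2d:
    """3x3 (or 1x1) same-padding convolution with He-normal initialisation."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, std, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        self._x = win
        return np.einsum("ncijkl,ockl->noij", win, self.w, optimize=True) \
            + self.b[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        self.gw += np.einsum("noij,ncijkl->ockl", gy, self._x, optimize=True)
        self.gb += gy.sum(axis=(0, 2, 3))
        gyp = np.pad(gy, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = sliding_window_view(gyp, (k, k), axis=(2, 3))
        wflip = self.w[:, :, ::-1, ::-1]
        return np.einsum("noijkl,ockl->ncij", gwin, wflip, optimize=True)

    def params(self):
        return [("w", self), ("b", self)]


class LeakyReLU:
    """Slope 0.1 on the negative side keeps units recoverable after the
    large sum-scaled loss gradients of the first training steps."""

    def forward(self, x):
        self._m = np.where(x > 0, 1.0, 0.1)
        return x * self._m

    def backward(self, gy):
        return gy * self._m


class AvgPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) / 4.0


class UpsampleNearest2:
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SmallEncoderDecoder:
    """3-level encoder-decoder with skip connections, 2-channel logits out.

    Two 2x poolings give the deepest features a receptive field wide enough
    to see a nucleus from across its expansion ring.
    """

    def __init__(self, n_in: int, width: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = width
        self.enc1 = Conv2d(n_in, w, 3, rng)
        self.enc2 = Conv2d(w, 2 * w, 3, rng)
        self.enc3 = Conv2d(2 * w, 4 * w, 3, rng)
        self.dec2 = Conv2d(6 * w, 2 * w, 3, rng)
        self.dec1 = Conv2d(3 * w, w, 3, rng)
        self.out = Conv2d(w, 2, 1, rng)
        self.r1, self.r2, self.r3 = LeakyReLU(), LeakyReLU(), LeakyReLU()
        self.r4, self.r5 = LeakyReLU(), LeakyReLU()
        self.pool1, self.pool2 = AvgPool2(), AvgPool2()
        self.up3, self.up2 = UpsampleNearest2(), UpsampleNearest2()
        self.width = width
        self.n_in = n_in

    # -- parameter access -------------------------------------------------
    def convs(self):
        return [self.enc1, self.enc2, self.enc3, self.dec2, self.dec1, self.out]

    def parameters(self) -> dict:
        out = {}
        for i, c in enumerate(self.convs()):
            out[f"conv{i}.w"] = c.w
            out[f"conv{i}.b"] = c.b
        return out

    def gradients(self) -> dict:
        out = {}
        for i, c in enumerate(self.convs()):
            out[f"conv{i}.w"] = c.gw
            out[f"conv{i}.b"] = c.gb
        return out

    def zero_grad(self):
        for c in self.convs():
            c.gw[...] = 0.0
            c.gb[...] = 0.0

    def load_parameters(self, params: dict):
        for i, c in enumerate(self.convs()):
            c.w[...] = params[f"conv{i}.w"]
            c.b[...] = params[f"conv{i}.b"]

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.n_in:
            raise ContractViolation(
                f"expected input (n_cells, {self.n_in}, h, w), got {x.shape}")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ContractViolation("patch side must be divisible by 4 (two 2x poolings)")
        a1 = self.r1.forward(self.enc1.forward(x))
        a2 = self.r2.forward(self.enc2.forward(self.pool1.forward(a1)))
        a3 = self.r3.forward(self.enc3.forward(self.pool2.forward(a2)))
        d2 = self.r4.forward(self.dec2.forward(
            np.concatenate([a2, self.up3.forward(a3)], axis=1)))
        d1 = self.r5.forward(self.dec1.forward(
            np.concatenate([a1, self.up2.forward(d2)], axis=1)))
        return self.out.forward(d1)

    def backward_logits(self, glogits: np.ndarray) -> None:
        w = self.width
        g1 = self.dec1.backward(self.r5.backward(self.out.backward(glogits)))
        ga1, gu2 = g1[:, :w], g1[:, w:]
        g2 = self.dec2.backward(self.r4.backward(self.up2.backward(gu2)))
        ga2, gu3 = g2[:, : 2 * w], g2[:, 2 * w:]
        ga2 = ga2 + self.pool2.backward(
            self.enc3.backward(self.r3.backward(self.up3.backward(gu3))))
        ga1 = ga1 + self.pool1.backward(
            self.enc2.backward(self.r2.backward(ga2)))
        self.enc1.backward(self.r1.backward(ga1))


_BACKBONES = {"small_encoder_decoder": SmallEncoderDecoder}


def register_backbone(name: str, factory) -> None:
    _BACKBONES[name] = factory


def make_backbone(name: str, n_in: int, **kwargs):
    if name not in _BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(_BACKBONES)}")
    return _BACKBONES[name](n_in, **kwargs)


def softmax2(logits: np.ndarray):
    """Numerically stable softmax over the 2-channel axis; returns (bg, fg)."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=1, keepdims=True)
    return p[:, 0], p[:, 1]


def forward(batch: PatchBatch, model) -> InstanceProbabilities:
    """Run the backbone on a patch; softmax-normalised per-cell probabilities."""
    logits = model.forward_logits(batch.network_input())
    if logits.shape != (len(batch.cell_ids), 2) + batch.expression.shape[:2]:
        raise ContractViolation(f"backbone output has wrong shape {logits.shape}")
    bg, fg = softmax2(logits)
    return InstanceProbabilities(foreground=fg, background=bg)


def assemble_segmentation(probs: InstanceProbabilities, cell_ids) -> np.ndarray:
    """Pixel-wise argmax over {mean background} u {per-cell foreground}.

    Background predictions are averaged across cells; ties favour background,
    then the lowest cell id.
    """
    if len(cell_ids) < 1:
        raise ValueError("need at least one cell")
    order = np.argsort(np.asarray(cell_ids, dtype=np.int64), kind="stable")
    mean_bg = probs.background.mean(axis=0)
    stack = np.concatenate([mean_bg[None], probs.foreground[order]], axis=0)
    winner = np.argmax(stack, axis=0)  # first maximum wins: bg, then low ids
    ids = np.concatenate([[0], np.asarray(cell_ids)[order]])
    return ids[winner].astype(np.int32)


# ---------------------------------------------------------------------------
# checkpointing


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(model, path, cfg: dict | None = None) -> None:
    params = {k: v for k, v in model.parameters().items()}
    meta = {"backbone": type(model).__name__, "n_in": model.n_in,
            "width": model.width, "config_hash": config_hash(cfg or {})}
    np.savez(path, __meta__=json.dumps(meta), **params)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    model = SmallEncoderDecoder(meta["n_in"], width=meta["width"])
    model.load_parameters({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
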