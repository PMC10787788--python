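"""The six biologically-informed training losses and their weighted sum.

Every loss is a function of the per-cell soft foreground probabilities
(clipped to [eps, 1-eps] before logarithms) and returns both its value and
its analytic gradient with respect to those probabilities, so the backward
pass and the finite-difference gradient checks share one code path.

Conventions: the three cross-entropy losses (nuclei encapsulation,
cell calling, positive marker) are pixel means averaged over cells, for
patch-size invariance; the over-segmentation, overlap, and negative-marker
losses are pixel sums with their explicit 1/M and 1/(M h w) normalisations.
The over-segmentation and overlap losses hinge to zero when their total sum
is nonpositive.  The negative-marker loss carries a constant sigmoid(-0.5)
floor on non-marker pixels; it contributes no gradient there.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .config import LossWeights

EPS = 1e-7


def _clip(p):
    return np.clip(p, EPS, 1.0 - EPS)


def _bce(target: np.ndarray, p: np.ndarray, reduction: str = "sum"):
    """Binary cross-entropy over all cells and pixels; value and grad wrt p.

    ``reduction="sum"`` (divided by the number of cells) keeps the loss at
    the same per-pixel scale as the sigmoid-sum losses, which is what makes
    the marker/cell-calling growth signals able to counter them during
    training; ``reduction="mean"`` gives the per-pixel average (ln 2 at a
    uniform 0.5 prediction).
    """
    t = target.astype(np.float64)
    pc = _clip(p)
    M = p.shape[0] if p.ndim == 3 else 1
    n = p.size if reduction == "mean" else M
    value = float((-t * np.log(pc) - (1.0 - t) * np.log(1.0 - pc)).sum()) / n
    grad = (-t / pc + (1.0 - t) / (1.0 - pc)) / n
    grad = np.where((p > EPS) & (p < 1.0 - EPS), grad, 0.0)
    return value, grad


def loss_nuclei_encapsulation(x_nuc: np.ndarray, y: np.ndarray,
                              reduction: str = "sum"):
    """BCE between the patch's nucleus mask and the predicted segmentation.

    Unlike the per-cell losses, this one compares a single aggregated
    prediction (the per-pixel mean of the per-cell foregrounds) against the
    union nucleus mask of the patch, so its off-nucleus penalty on any one
    cell scales with 1/M and does not overwhelm the cell-calling growth
    signal.  ``x_nuc`` may be given per cell (M, h, w) — the union is taken —
    or directly as an (h, w) mask; ``y`` is (M, h, w).
    """
    if x_nuc.ndim == 3:
        x_nuc = x_nuc.max(axis=0)
    M = y.shape[0]
    agg = y.mean(axis=0)
    t = x_nuc.astype(np.float64)
    pc = _clip(agg)
    n = agg.size if reduction == "mean" else 1
    value = float((-t * np.log(pc) - (1.0 - t) * np.log(1.0 - pc)).sum()) / n
    g_agg = (-t / pc + (1.0 - t) / (1.0 - pc)) / n
    g_agg = np.where((agg > EPS) & (agg < 1.0 - EPS), g_agg, 0.0)
    grad = np.broadcast_to(g_agg / M, y.shape).copy()
    return value, grad


def loss_cell_calling(e: np.ndarray, y: np.ndarray, reduction: str = "sum"):
    """BCE between each cell's expansion mask and its predicted foreground,
    averaged over the M cells of the patch."""
    return _bce(e, y, reduction)


def loss_pos_marker(m_pos: np.ndarray, y: np.ndarray, reduction: str = "sum"):
    """BCE between each cell's dilated positive-marker map and its foreground,
    averaged over cells."""
    return _bce(m_pos, y, reduction)


def loss_oversegmentation(q: np.ndarray, x_nuc: np.ndarray):
    """Penalise cytoplasmic prediction mass exceeding nuclear mass.

    p_nuc,c  = sum_ij sigmoid(q * x_nuc - 0.5)
    p_cyto,c = sum_ij sigmoid(q * (1 - x_nuc) - 0.5)
    L = (1/M) sum_c (p_cyto,c - p_nuc,c)  if that (unscaled) sum > 0, else 0.
    """
    M = q.shape[0]
    x = x_nuc.astype(np.float64)
    s_cyto = expit(q * (1.0 - x) - 0.5)
    s_nuc = expit(q * x - 0.5)
    total = float((s_cyto - s_nuc).sum())
    if total <= 0.0:
        return 0.0, np.zeros_like(q)
    grad = (s_cyto * (1.0 - s_cyto) * (1.0 - x) - s_nuc * (1.0 - s_nuc) * x) / M
    return total / M, grad


def loss_overlap(q: np.ndarray, x_union: np.ndarray):
    """Penalise multiple cells predicting the same non-nuclear pixel.

    s_ij = -(1 - x_ij) + sum_c sigmoid(q_ijc (1 - x_ij) - 0.5), with x the
    union of all nuclei; L = sum_ij s_ij / (M h w) if the sum > 0, else 0.
    """
    M, h, w = q.shape
    x = x_union.astype(np.float64)
    s = expit(q * (1.0 - x)[None] - 0.5)
    total = float(s.sum() - (1.0 - x).sum())
    if total <= 0.0:
        return 0.0, np.zeros_like(q)
    grad = s * (1.0 - s) * (1.0 - x)[None] / (M * h * w)
    return total / (M * h * w), grad


def loss_neg_marker(m_neg: np.ndarray, q: np.ndarray):
    """L = (1/M) sum_c sum_ij sigmoid(q * m_neg - 0.5)."""
    M = q.shape[0]
    m = m_neg.astype(np.float64)
    s = expit(q * m - 0.5)
    grad = s * (1.0 - s) * m / M
    return float(s.sum()) / M, grad


def total_loss(parts: dict, weights: LossWeights = LossWeights()):
    """Weighted sum of the six named loss values."""
    total = 0.0
    for name in ("ne", "cc", "os", "ov", "pos", "neg"):
        value = parts[name]
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss component {name!r}: {value}")
        total += getattr(weights, name) * value
    return total


def compute_all(q: np.ndarray, x_nuc: np.ndarray, e: np.ndarray,
                m_pos: np.ndarray, m_neg: np.ndarray, x_union: np.ndarray,
                weights: LossWeights = LossWeights()):
    """All six losses on one patch; returns (parts dict, total, grad wrt q).

    ``q`` doubles as the soft predicted segmentation y-hat in the
    cross-entropy terms, since training requires differentiable predictions.
    """
    parts = {}
    grads = np.zeros_like(q)
    for name, (fn, target) in {
        "ne": (loss_nuclei_encapsulation, x_nuc),
        "cc": (loss_cell_calling, e),
        "pos": (loss_pos_marker, m_pos),
    }.items():
        v, g = fn(target, q)
        parts[name] = v
        grads += getattr(weights, name) * g
    for name, (fn, other) in {
        "os": (loss_oversegmentation, x_nuc),
        "ov": (loss_overlap, x_union),
    }.items():
        v, g = fn(q, other)
        parts[name] = v
        grads += getattr(weights, name) * g
    v, g = loss_neg_marker(m_neg, q)
    parts["neg"] = v
    grads += weights.neg * g
    return parts, total_loss(parts, weights), grads
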