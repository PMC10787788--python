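"""Self-supervised training: patch stream, augmentation, and the Adam loop.

Training uses only primary-grid patches that contain nuclei.  Each emitted
sample applies one of the 8 dihedral transforms (optional horizontal flip x
rotation by 0/90/180/270 degrees), chosen uniformly, consistently across the
expression patch, nucleus masks, expansion masks, and marker maps.  Raw
counts are fed without normalisation.  Optimisation is Adam (classic L2
weight decay added to the gradient) at a fixed learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ExpansionConfig, TrainConfig
from .losses import compute_all
from .markers import MarkerSets, marker_maps_for_cell
from .model import PatchBatch, forward, softmax2
from .morphology import expansion_mask


@dataclass
class TrainingPatch:
    """A patch with everything the losses need, precomputed once."""

    expression: np.ndarray        # h x w x n_genes
    per_cell_nuclei: np.ndarray   # M x h x w binary
    expansions: np.ndarray        # M x h x w binary
    m_pos: np.ndarray             # M x h x w binary
    m_neg: np.ndarray             # M x h x w binary
    cell_ids: list
    origin: tuple = (0, 0)

    @property
    def x_union(self) -> np.ndarray:
        return self.per_cell_nuclei.any(axis=0)

    def batch(self) -> PatchBatch:
        return PatchBatch(self.expression, self.per_cell_nuclei, self.cell_ids)


def prepare_training_patch(patch, summaries_by_id: dict, markers: MarkerSets,
                           gene_index, expansion_cfg: ExpansionConfig,
                           expansions_full: dict | None = None) -> TrainingPatch:
    """Assemble per-cell nuclei, expansions, and marker maps for one patch.

    ``expansions_full`` optionally maps cell_id -> full-image expansion mask;
    when given, the patch crop of that mask is used so that expansions keep
    their full geometry across patch borders.
    """
    labels = [int(l) for l in np.unique(patch.nuclei) if l > 0]
    h, w = patch.nuclei.shape
    nuclei = np.stack([patch.nuclei == l for l in labels])
    expansions = []
    m_pos, m_neg = [], []
    for i, lab in enumerate(labels):
        s = summaries_by_id[lab]
        if expansions_full is not None and lab in expansions_full:
            r0, c0 = patch.origin
            full = expansions_full[lab]
            crop = np.zeros((h, w), dtype=bool)
            r1 = min(r0 + h, full.shape[0])
            c1 = min(c0 + w, full.shape[1])
            crop[: r1 - r0, : c1 - c0] = full[r0:r1, c0:c1]
            exp = crop | nuclei[i]
        else:
            exp = expansion_mask(nuclei[i], s.elongated, s.eccentricity,
                                 s.orientation, expansion_cfg)
        expansions.append(exp)
        mtype = s.assigned_type if s.assigned_type in markers.positive \
            else next(iter(sorted(markers.positive)))
        mp, mn = marker_maps_for_cell(markers, mtype, patch.expression,
                                      gene_index, exp)
        m_pos.append(mp)
        m_neg.append(mn)
    return TrainingPatch(
        expression=patch.expression,
        per_cell_nuclei=nuclei,
        expansions=np.stack(expansions),
        m_pos=np.stack(m_pos),
        m_neg=np.stack(m_neg),
        cell_ids=labels,
        origin=patch.origin,
    )


# ---------------------------------------------------------------------------
# augmentation: the 8 elements of the dihedral group D4


def _transform2d(arr: np.ndarray, flip: bool, k: int, axes):
    if flip:
        arr = np.flip(arr, axis=axes[1])
    return np.rot90(arr, k=k, axes=axes)


def augment_patch(tp: TrainingPatch, flip: bool, k: int) -> TrainingPatch:
    """Apply one dihedral transform consistently to all patch tensors."""
    return TrainingPatch(
        expression=_transform2d(tp.expression, flip, k, (0, 1)).copy(),
        per_cell_nuclei=_transform2d(tp.per_cell_nuclei, flip, k, (1, 2)).copy(),
        expansions=_transform2d(tp.expansions, flip, k, (1, 2)).copy(),
        m_pos=_transform2d(tp.m_pos, flip, k, (1, 2)).copy(),
        m_neg=_transform2d(tp.m_neg, flip, k, (1, 2)).copy(),
        cell_ids=tp.cell_ids,
        origin=tp.origin,
    )


def make_training_stream(training_patches: list, seed: int, n_samples: int):
    """Deterministic shuffled, augmented sample stream over primary patches.

    Cycles with per-epoch reshuffling when ``n_samples`` exceeds the number
    of patches.  Each sample gets one of the 8 augmentations uniformly.
    """
    usable = [tp for tp in training_patches if len(tp.cell_ids) > 0]
    if not usable:
        raise ValueError("no patches with nuclei available for training")
    rng = np.random.default_rng(seed)
    emitted = 0
    while emitted < n_samples:
        order = rng.permutation(len(usable))
        for idx in order:
            if emitted >= n_samples:
                return
            aug = rng.integers(8)
            flip, k = bool(aug // 4), int(aug % 4)
            yield augment_patch(usable[idx], flip, k)
            emitted += 1


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    """Adam with classic L2 weight decay and global gradient-norm clipping.

    Clipping guards against the very large gradients the sum-scaled losses
    emit in the first steps, before the hinge terms deactivate.
    """

    def __init__(self, params: dict, lr: float, beta1: float, beta2: float,
                 weight_decay: float, clip_norm: float = 1.0):
        self.lr, self.b1, self.b2, self.wd = lr, beta1, beta2, weight_decay
        self.clip = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = self.clip / norm if (self.clip and norm > self.clip) else 1.0
        for k, p in params.items():
            g = grads[k] * scale + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def train(model, stream, config: TrainConfig) -> pd.DataFrame:
    """Run the training loop; returns the per-step loss log.

    The model is updated in place.  Raises on any non-finite loss, naming
    the offending component and step.
    """
    opt = Adam(model.parameters(), config.learning_rate, config.adam_beta1,
               config.adam_beta2, config.weight_decay)
    log = []
    for step, tp in enumerate(stream):
        if step >= config.n_iterations:
            break
        batch = tp.batch()
        model.zero_grad()
        logits = model.forward_logits(batch.network_input())
        bg, fg = softmax2(logits)
        try:
            parts, total, gq = compute_all(
                fg, tp.per_cell_nuclei.astype(np.float64), tp.expansions,
                tp.m_pos, tp.m_neg, tp.x_union, config.weights)
        except FloatingPointError as exc:
            raise FloatingPointError(f"at step {step}: {exc}") from exc
        # softmax backward: d total / d logits from d total / d fg
        gfg = gq * fg * (1.0 - fg)
        glogits = np.stack([-gfg, gfg], axis=1)
        model.backward_logits(glogits)
        opt.step(model.parameters(), model.gradients())
        log.append({"step": step, "total": total, **parts,
                    "n_cells": len(tp.cell_ids)})
    return pd.DataFrame(log, columns=["step", "total", "ne", "cc", "os",
                                      "ov", "pos", "neg", "n_cells"])
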