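"""Reference cell-type expression profiles and positive/negative marker sets.

Positive and negative markers of a cell type are the genes in the top and
bottom ``percentile`` of a per-type differential score (mean log1p expression
of the type minus the mean log1p expression across all other types).  Positive
markers shared by too many types are removed: for training markers the cutoff
is inclusive at one third of types; for the purity-evaluation markers it is
strict at 25%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class ReferenceProfile:
    """Cell-type x gene mean-expression matrix with per-type elongation flags."""

    mean_expression: pd.DataFrame  # rows = cell types, columns = genes
    elongated_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.mean_expression.values < 0).any():
            raise ValueError("reference profile must be nonnegative")
        zero_rows = self.mean_expression.sum(axis=1) == 0
        if zero_rows.any():
            bad = list(self.mean_expression.index[zero_rows])
            raise ValueError(f"all-zero cell-type rows rejected: {bad}")

    @property
    def cell_types(self) -> list:
        return list(self.mean_expression.index)

    @property
    def genes(self) -> list:
        return list(self.mean_expression.columns)

    def is_elongated(self, cell_type: str) -> bool:
        return bool(self.elongated_flags.get(cell_type, False))

    def restrict_genes(self, panel) -> "ReferenceProfile":
        """Intersect the profile's gene panel with ``panel`` (order of panel kept)."""
        common = [g for g in panel if g in self.mean_expression.columns]
        return ReferenceProfile(self.mean_expression[common], dict(self.elongated_flags))

    def to_csv(self, path) -> None:
        self.mean_expression.to_csv(path)

    @classmethod
    def from_csv(cls, path, elongated_type_names=()) -> "ReferenceProfile":
        df = pd.read_csv(path, index_col=0)
        flags = {t: (t in set(elongated_type_names)) for t in df.index}
        return cls(df, flags)


@dataclass
class MarkerSets:
    """Positive/negative marker genes per cell type."""

    positive: dict  # cell_type -> frozenset of genes
    negative: dict
    percentile: float
    commonality_threshold: float

    def __post_init__(self):
        for t in self.positive:
            if self.positive[t] & self.negative.get(t, frozenset()):
                raise ValueError(f"positive and negative markers overlap for {t!r}")

    def to_json(self, path) -> None:
        payload = {
            "percentile": self.percentile,
            "commonality_threshold": self.commonality_threshold,
            "positive": {t: sorted(s) for t, s in self.positive.items()},
            "negative": {t: sorted(s) for t, s in self.negative.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def differential_scores(profile: ReferenceProfile) -> pd.DataFrame:
    """Per-type score: mean log1p expression minus the mean over other types."""
    log = np.log1p(profile.mean_expression.astype(float))
    n = len(log)
    if n == 1:
        return log
    total = log.sum(axis=0)
    other_mean = (total - log) / (n - 1)
    return log - other_mean


def _ranked_candidates(scores: pd.Series, count: int, top: bool) -> list:
    # deterministic: score order, then gene-name lexicographic at ties
    order = sorted(scores.index, key=lambda g: ((-scores[g] if top else scores[g]), g))
    return order[:count]


def derive_markers(
    profile: ReferenceProfile,
    percentile: float = 0.10,
    commonality_threshold: float = 1.0 / 3.0,
    commonality_strict: bool = False,
) -> MarkerSets:
    """Derive top/bottom-percentile marker sets with a commonality filter.

    ``commonality_strict=False`` removes positive candidates present in at
    least ``commonality_threshold`` of types (training semantics);
    ``commonality_strict=True`` removes those present in strictly more than
    the threshold (purity-evaluation semantics).
    """
    if not (0.0 < percentile < 0.5):
        raise ValueError("percentile must be in (0, 0.5)")
    scores = differential_scores(profile)
    n_types, n_genes = scores.shape
    count = math.ceil(percentile * n_genes)
    if count == 0:
        raise ValueError("percentile yields empty marker sets")

    pos, neg = {}, {}
    for t in scores.index:
        row = scores.loc[t]
        pos[t] = _ranked_candidates(row, count, top=True)
        # disjointness: a boundary-tied gene claimed as positive is skipped
        bottom = [g for g in _ranked_candidates(row, len(row), top=False)
                  if g not in set(pos[t])]
        neg[t] = bottom[:count]
        if not pos[t] or not neg[t]:
            raise ValueError(f"empty marker set for cell type {t!r}")

    if n_types > 1:
        counts: dict = {}
        for t in pos:
            for g in pos[t]:
                counts[g] = counts.get(g, 0) + 1
        # a gene in a single type's set is specific, not "common": require >= 2
        cut = max(commonality_threshold * n_types, 2.0 - 1e-12)
        if commonality_strict:
            common = {g for g, c in counts.items() if c > cut}
        else:
            common = {g for g, c in counts.items() if c >= cut}
        pos = {t: [g for g in genes if g not in common] for t, genes in pos.items()}

    return MarkerSets(
        positive={t: frozenset(g) for t, g in pos.items()},
        negative={t: frozenset(g) for t, g in neg.items()},
        percentile=percentile,
        commonality_threshold=commonality_threshold,
    )


def derive_purity_markers(profile: ReferenceProfile, percentile: float = 0.10,
                          commonality_threshold: float = 0.25) -> MarkerSets:
    """Markers for expression-purity evaluation (strict >25% commonality filter)."""
    scores = differential_scores(profile)
    if len(scores) > 1 and np.allclose(scores.values, 0.0):
        raise ValueError("no discriminative markers: identical profiles for all types")
    return derive_markers(profile, percentile=percentile,
                          commonality_threshold=commonality_threshold,
                          commonality_strict=True)


_DILATE_3X3 = np.ones((3, 3), dtype=bool)


def marker_maps_for_cell(markers: MarkerSets, cell_type: str,
                         patch_counts: np.ndarray, gene_index,
                         expansion: np.ndarray):
    """Binary positive/negative marker maps for one cell on one patch.

    A pixel is 1 iff any transcript of any marker gene of that polarity was
    rasterised there; the map is masked by the cell's expansion mask and then
    dilated with a 3x3 structuring element.
    """
    if cell_type not in markers.positive:
        raise KeyError(f"unknown cell type {cell_type!r}")
    if expansion.shape != patch_counts.shape[:2]:
        raise ValueError("expansion mask shape must match patch lateral shape")
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    out = []
    for polarity in (markers.positive[cell_type], markers.negative[cell_type]):
        idx = [gene_pos[g] for g in polarity if g in gene_pos]
        if idx:
            m = patch_counts[:, :, idx].sum(axis=2) > 0
        else:
            m = np.zeros(patch_counts.shape[:2], dtype=bool)
        m &= expansion.astype(bool)
        m = ndimage.binary_dilation(m, structure=_DILATE_3X3)
        out.append(m)
    return out[0], out[1]
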