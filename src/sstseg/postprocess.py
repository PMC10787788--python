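"""Whole-image assembly of patch predictions, per-cell morphological
refinement, and transcript-to-cell assignment.

Patch predictions from the two half-overlapping grids are merged by taking,
at each pixel, the label predicted by the patch whose centre is nearest
(primary grid wins ties, then the lower origin).  Each cell is then refined:
closing with a disc in a 5x5 window (two dilations then two erosions),
keeping the connected component that overlaps its nucleus most, hole-filling
it, and unioning the nucleus back in, so every final cell is one connected
component containing its nucleus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphology import circular_kernel

FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def merge_patch_predictions(predictions: list, image_shape: tuple) -> np.ndarray:
    """Merge per-patch label maps into a full-image mask.

    ``predictions`` is a list of (label_map, origin, grid) with grid
    "primary" or "shifted".  Per pixel, the retained label comes from the
    patch with the nearest centre; iteration order (primary first, then
    ascending origin) plus a strict-improvement rule implements the
    deterministic tie-break.
    """
    if not predictions:
        raise ValueError("no patch predictions given")
    H, W = image_shape
    out = np.zeros((H, W), dtype=np.int32)
    best = np.full((H, W), np.inf)
    ordered = sorted(predictions,
                     key=lambda p: (0 if p[2] == "primary" else 1, p[1]))
    for labels, (r0, c0), _grid in ordered:
        ph, pw = labels.shape
        r1, c1 = min(r0 + ph, H), min(c0 + pw, W)
        if r1 <= r0 or c1 <= c0:
            continue
        cy, cx = r0 + ph / 2.0, c0 + pw / 2.0
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2
        win = dist < best[r0:r1, c0:c1]
        out[r0:r1, c0:c1][win] = labels[: r1 - r0, : c1 - c0][win]
        best[r0:r1, c0:c1][win] = dist[win]
    return out


_CLOSE_KERNEL = circular_kernel(5)


def refine_cell(raw: np.ndarray, nucleus: np.ndarray) -> np.ndarray:
    """Morphologically refine one cell's binary mask.

    Steps: two dilations then two erosions with a 5x5 disc; keep the
    connected component with the largest nucleus overlap (ties: larger
    component, then scan order); fill its holes; union the nucleus.
    An empty raw mask falls back to the nucleus alone.
    """
    nucleus = nucleus.astype(bool)
    if not nucleus.any():
        raise ValueError("nucleus mask is empty")
    raw = raw.astype(bool)
    if not raw.any():
        return nucleus.copy()
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(raw, structure=_CLOSE_KERNEL, iterations=2),
        structure=_CLOSE_KERNEL, iterations=2)
    closed |= raw  # closing is extensive; restore pixels lost to image-border erosion
    comp, n = ndimage.label(closed, structure=FOUR_CONN)
    if n == 0:
        return nucleus.copy()
    overlaps = ndimage.sum_labels(nucleus, comp, index=np.arange(1, n + 1))
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    order = sorted(range(n), key=lambda i: (-overlaps[i], -sizes[i], i))
    keep = comp == order[0] + 1
    if overlaps[order[0]] == 0:
        return nucleus.copy()
    filled = ndimage.binary_fill_holes(keep, structure=FOUR_CONN)
    return filled | nucleus


def refine_all(raw_labels: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Refine every cell and paste back into a single label image.

    Contested pixels go to the first (lowest-label) claimant; nucleus pixels
    always keep their own label.
    """
    out = np.zeros_like(raw_labels, dtype=np.int32)
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    for lab in labels:
        mask = refine_cell(raw_labels == lab, nuclei == lab)
        out[mask & (out == 0)] = lab
    out[nuclei > 0] = nuclei[nuclei > 0]
    return out


def map_transcripts_to_cells(transcripts: pd.DataFrame, mask: np.ndarray,
                             gene_panel):
    """Assign transcripts to segmented cells by point-in-mask lookup.

    Returns (cells x genes count DataFrame, fraction of records assigned).
    Every nucleus-bearing label gets a row even if no transcript maps to it.
    """
    gene_panel = list(gene_panel)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    matrix = pd.DataFrame(0, index=labels.tolist(), columns=gene_panel, dtype=np.int64)
    total = len(transcripts)
    if total == 0:
        return matrix, 0.0
    rows = np.floor(transcripts["y"].to_numpy(float)).astype(int)
    cols = np.floor(transcripts["x"].to_numpy(float)).astype(int)
    genes = transcripts["gene"].to_numpy()
    H, W = mask.shape
    inb = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    cell = np.zeros(total, dtype=np.int64)
    cell[inb] = mask[rows[inb], cols[inb]]
    assigned = 0
    gset = set(gene_panel)
    tally: dict = {}
    for c, g in zip(cell, genes):
        if c > 0 and g in gset:
            tally[(c, g)] = tally.get((c, g), 0) + 1
            assigned += 1
    for (c, g), v in tally.items():
        matrix.loc[c, g] = v
    return matrix, assigned / total
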