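"""Synthetic subcellular spatial transcriptomics generator.

Emulates the data model the segmentation pipeline consumes: a detected
transcript table (x, y, gene, qv), a nuclei instance-label mask, a reference
cell-type x gene profile, and full ground truth (cell masks, types, and the
cell of origin of every transcript).

Cells are non-overlapping ellipses; each cell's nucleus is a concentric
ellipse scaled to ``nucleus_to_cell_area_ratio`` of the cell area.  Elongated
cell types draw their eccentricity from a high range, round types from a low
range, mirroring the observation that elongated cell types have more
eccentric nuclei.  Transcript counts are Poisson; gene identities follow the
type's profile with a disjoint block of marker genes enriched multiplicatively;
positions are uniform within the cell mask, with uniform background noise.
All randomness flows from ``SimConfig.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .markers import ReferenceProfile

BACKGROUND = 0  # origin label for noise transcripts


class PlacementError(RuntimeError):
    pass


@dataclass
class GroundTruth:
    cell_mask: np.ndarray          # H x W int labels, 0 = background
    nuclei_mask: np.ndarray        # H x W int labels, subset of cell_mask
    cell_types: dict               # cell_id -> type name
    transcript_cell_of_origin: np.ndarray  # per transcript record, 0 = background

    def __post_init__(self):
        inside = self.nuclei_mask > 0
        if not np.array_equal(self.nuclei_mask[inside], self.cell_mask[inside]):
            raise ValueError("every nucleus pixel must lie in its own cell")


@dataclass
class SimulatedDataset:
    transcripts: pd.DataFrame      # columns x, y, gene, qv
    nuclei_mask: np.ndarray
    profile: ReferenceProfile
    truth: GroundTruth


def _type_names(n: int) -> list:
    return [f"type_{i}" for i in range(n)]


def _gene_names(n: int) -> list:
    width = max(3, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def type_rate_multipliers(config: SimConfig) -> np.ndarray:
    """Per-type RNA-content multipliers: adjacent types differ by
    ``transcript_rate_spread``-fold, centred so the geometric mean is 1."""
    k = np.arange(config.n_cell_types) - (config.n_cell_types - 1) / 2.0
    return config.transcript_rate_spread ** k


def make_reference_profile(config: SimConfig, rng: np.random.Generator) -> ReferenceProfile:
    """Block-marker design: type t's disjoint gene block is enriched
    ``marker_enrichment_fold``-fold over a common baseline, and the marker
    blocks of the other types are depleted by the same fold (a type's
    negative markers are genuinely rare in its cells, as in real reference
    profiles); rows are scaled to the expected per-cell transcript count."""
    types = _type_names(config.n_cell_types)
    genes = _gene_names(config.n_genes)
    block = int(np.ceil(config.n_genes / config.n_cell_types))
    base = rng.uniform(0.5, 1.5, size=config.n_genes)
    mult = type_rate_multipliers(config)
    rows = []
    for i in range(config.n_cell_types):
        row = base.copy()
        for j in range(config.n_cell_types):
            sl = slice(j * block, (j + 1) * block)
            row[sl] *= (config.marker_enrichment_fold if j == i
                        else 1.0 / config.marker_enrichment_fold)
        rows.append(row / row.sum() * config.mean_transcripts_per_cell * mult[i])
    df = pd.DataFrame(rows, index=types, columns=genes)
    flags = {t: (t in config.elongated_type_names) for t in types}
    return ReferenceProfile(df, flags)


def _ellipse_mask(H, W, cy, cx, a, b, theta) -> np.ndarray:
    """Pixels whose centres fall inside the rotated ellipse with semi-axes a, b."""
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy + 0.5 - cy, xx + 0.5 - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_cells(config: SimConfig, rng: np.random.Generator):
    H, W = config.image_height, config.image_width
    cell_mask = np.zeros((H, W), dtype=np.int32)
    nuclei_mask = np.zeros((H, W), dtype=np.int32)
    types = _type_names(config.n_cell_types)
    cell_types: dict = {}
    summaries = []

    mean_area = 0.45 * H * W / max(config.n_cells, 1)
    max_attempts = 200 * max(config.n_cells, 1)
    attempts = 0
    cid = 0
    while cid < config.n_cells:
        if attempts >= max_attempts:
            density = config.n_cells * mean_area / (H * W)
            raise PlacementError(
                f"could not place {config.n_cells} non-overlapping cells after "
                f"{max_attempts} attempts; requested packing fraction ~{density:.2f} "
                f"is too dense for a {H}x{W} image")
        attempts += 1
        ctype = types[rng.integers(config.n_cell_types)]
        lo, hi = (config.eccentricity_range_elongated
                  if ctype in config.elongated_type_names
                  else config.eccentricity_range_round)
        ecc = rng.uniform(lo, hi)
        area = mean_area * rng.uniform(0.7, 1.3)
        # area = pi*a*b with b = a*sqrt(1-ecc^2)
        ratio = np.sqrt(1.0 - ecc ** 2)
        a = np.sqrt(area / (np.pi * ratio))
        b = a * ratio
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a, H - a) if H > 2 * a else H / 2
        cx = rng.uniform(a, W - a) if W > 2 * a else W / 2
        mask = _ellipse_mask(H, W, cy, cx, a, b, theta)
        if mask.sum() < 4 or (cell_mask[mask] != 0).any():
            continue
        scale = np.sqrt(config.nucleus_to_cell_area_ratio)
        nuc = _ellipse_mask(H, W, cy, cx, a * scale, b * scale, theta)
        nuc &= mask
        if nuc.sum() < 1:
            continue
        cid += 1
        cell_mask[mask] = cid
        nuclei_mask[nuc] = cid
        cell_types[cid] = ctype
        summaries.append((cid, ctype, mask))
    return cell_mask, nuclei_mask, cell_types, summaries


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset; deterministic given ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    profile = make_reference_profile(config, rng)
    genes = np.asarray(profile.genes)
    H, W = config.image_height, config.image_width

    cell_mask, nuclei_mask, cell_types, summaries = _place_cells(config, rng)

    xs, ys, gs, origins = [], [], [], []
    probs = profile.mean_expression.values / \
        profile.mean_expression.values.sum(axis=1, keepdims=True)
    type_row = {t: i for i, t in enumerate(profile.cell_types)}
    mult = type_rate_multipliers(config)
    for cid, ctype, mask in summaries:
        n = rng.poisson(config.mean_transcripts_per_cell * mult[type_row[ctype]])
        if n == 0:
            continue
        rows, cols = np.nonzero(mask)
        pick = rng.integers(len(rows), size=n)
        ys.append(rows[pick] + rng.uniform(0, 1, size=n))
        xs.append(cols[pick] + rng.uniform(0, 1, size=n))
        gs.append(rng.choice(genes, size=n, p=probs[type_row[ctype]]))
        origins.append(np.full(n, cid, dtype=np.int32))

    n_bg = rng.poisson(config.background_noise_rate * H * W)
    if n_bg > 0:
        ys.append(rng.uniform(0, H, size=n_bg))
        xs.append(rng.uniform(0, W, size=n_bg))
        gs.append(rng.choice(genes, size=n_bg))
        origins.append(np.full(n_bg, BACKGROUND, dtype=np.int32))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        g = np.concatenate(gs)
        origin = np.concatenate(origins)
    else:
        x = y = np.empty(0)
        g = np.empty(0, dtype=object)
        origin = np.empty(0, dtype=np.int32)

    qv = rng.uniform(20.0, 40.0, size=len(x))  # all records pass the default QV filter
    transcripts = pd.DataFrame({"x": x, "y": y, "gene": g, "qv": qv})
    truth = GroundTruth(cell_mask=cell_mask, nuclei_mask=nuclei_mask,
                        cell_types=cell_types, transcript_cell_of_origin=origin)
    return SimulatedDataset(transcripts, nuclei_mask, profile, truth)


def profile_recovery_check(truth: GroundTruth, transcripts: pd.DataFrame,
                           profile: ReferenceProfile) -> dict:
    """Pearson correlation between each type's generating profile and the mean
    expression of its cells under the ground-truth transcript assignment.

    Types absent from the simulation are reported as ``None`` (missing),
    not raised.
    """
    genes = profile.genes
    gidx = {g: i for i, g in enumerate(genes)}
    per_cell: dict = {}
    origin = truth.transcript_cell_of_origin
    for rec_gene, cid in zip(transcripts["gene"].values, origin):
        if cid == BACKGROUND:
            continue
        vec = per_cell.setdefault(cid, np.zeros(len(genes)))
        if rec_gene in gidx:
            vec[gidx[rec_gene]] += 1

    result: dict = {}
    for t in profile.cell_types:
        cells = [c for c, ct in truth.cell_types.items() if ct == t]
        vecs = [per_cell[c] for c in cells if c in per_cell]
        if not vecs:
            result[t] = None
            continue
        mean_expr = np.mean(vecs, axis=0)
        ref = profile.mean_expression.loc[t].values.astype(float)
        if mean_expr.std() == 0 or ref.std() == 0:
            result[t] = None
            continue
        result[t] = float(np.corrcoef(mean_expr, ref)[0, 1])
    return result
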