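"""Segmentation evaluation across five complementary categories:
baseline characteristics, cell-expression purity, spatial diversity,
neighbour contamination, and replicability.

Shape metrics operate on a ``CellShape`` built from either a polygon or a
binary mask (mask boundaries are traced with marching squares so discrete
discs converge to the analytic circle identities):

    elongation   = W_bb / H_bb            (oriented min-area bounding box)
    circularity  = 4 pi A / P_convex^2
    sphericity   = R_I / R_C              (max inscribed / min enclosing radius)
    compactness  = 4 pi A / P_cell^2
    convexity    = P_convex / P_cell
    eccentricity = L_minor / L_major      (moment-fitted axes)
    solidity     = A / A_convex
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import measure

from .markers import MarkerSets, ReferenceProfile

SHAPE_METRIC_NAMES = ["area", "elongation", "circularity", "sphericity",
                      "compactness", "convexity", "eccentricity", "solidity"]


# ---------------------------------------------------------------------------
# shape geometry


def _polygon_second_moments(poly: Polygon):
    """Exact second central moments of a polygon via Green's theorem."""
    x, y = poly.exterior.coords.xy
    x, y = np.asarray(x), np.asarray(y)
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    cross = x0 * y1 - x1 * y0
    A = cross.sum() / 2.0  # signed; sign cancels in the ratios below
    cx = ((x0 + x1) * cross).sum() / (6.0 * A)
    cy = ((y0 + y1) * cross).sum() / (6.0 * A)
    Ixx = ((y0 ** 2 + y0 * y1 + y1 ** 2) * cross).sum() / 12.0  # integral of y^2
    Iyy = ((x0 ** 2 + x0 * x1 + x1 ** 2) * cross).sum() / 12.0  # integral of x^2
    Ixy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / 24.0
    # central second moments per unit area
    mxx = Iyy / A - cx ** 2
    myy = Ixx / A - cy ** 2
    mxy = Ixy / A - cx * cy
    return mxx, myy, mxy


def _axes_from_moments(mxx: float, myy: float, mxy: float):
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals = np.linalg.eigvalsh(cov)
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    return 4.0 * math.sqrt(lam_major), 4.0 * math.sqrt(lam_minor)


def _mask_to_polygon(mask: np.ndarray) -> Optional[Polygon]:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    best = max(contours, key=len)
    # find_contours yields (row, col); shift for the pad, swap to (x, y)
    xy = np.column_stack([best[:, 1] - 1, best[:, 0] - 1])
    if np.array_equal(xy[0], xy[-1]):
        xy = xy[:-1]
    # smooth the half-pixel marching-squares staircase with a short circular
    # moving average so perimeters of rasterised discs converge to the
    # analytic value; tiny shapes are left as-is
    if len(xy) >= 12:
        kernel = np.ones(5) / 5.0
        padded = np.vstack([xy[-2:], xy, xy[:2]])
        xy = np.column_stack([np.convolve(padded[:, 0], kernel, "valid"),
                              np.convolve(padded[:, 1], kernel, "valid")])
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly if (poly.geom_type == "Polygon" and poly.area > 0) else None


@dataclass
class CellShape:
    """Geometry of one cell: polygon boundary plus derived quantities."""

    polygon: Polygon
    area: float = field(init=False)
    perimeter: float = field(init=False)
    convex_area: float = field(init=False)
    convex_perimeter: float = field(init=False)
    bbox_sides: tuple = field(init=False)       # oriented min-area rectangle
    inscribed_radius: float = field(init=False)
    circumscribed_radius: float = field(init=False)
    major_axis: float = field(init=False)
    minor_axis: float = field(init=False)

    def __post_init__(self):
        poly = self.polygon
        if poly.area <= 0:
            raise ValueError("degenerate shape with zero area")
        self.area = poly.area
        self.perimeter = poly.exterior.length
        hull = poly.convex_hull
        self.convex_area = hull.area
        self.convex_perimeter = hull.exterior.length
        rect = shapely.oriented_envelope(poly)
        rc = np.asarray(rect.exterior.coords)
        s1 = float(np.linalg.norm(rc[1] - rc[0]))
        s2 = float(np.linalg.norm(rc[2] - rc[1]))
        # W_bb = the side closer to the x-axis direction; square -> either
        e1 = (rc[1] - rc[0]) / max(s1, 1e-12)
        if abs(e1[0]) >= abs(e1[1]):
            self.bbox_sides = (s1, s2)
        else:
            self.bbox_sides = (s2, s1)
        radius_line = shapely.maximum_inscribed_circle(poly)
        self.inscribed_radius = float(radius_line.length)
        self.circumscribed_radius = float(shapely.minimum_bounding_radius(poly))
        self.major_axis, self.minor_axis = _axes_from_moments(
            *_polygon_second_moments(poly))

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "CellShape":
        poly = _mask_to_polygon(mask)
        if poly is None:
            raise ValueError("mask has no traceable boundary")
        return cls(poly)

    @classmethod
    def circle(cls, radius: float, n_vertices: int = 2048) -> "CellShape":
        t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        return cls(Polygon(np.column_stack([radius * np.cos(t),
                                            radius * np.sin(t)])))


def shape_metrics(shape: CellShape) -> dict:
    """The eight morphology scalars for one cell."""
    w_bb, h_bb = shape.bbox_sides
    major = max(shape.major_axis, 1e-12)
    return {
        "area": shape.area,
        "elongation": w_bb / max(h_bb, 1e-12),
        "circularity": 4.0 * math.pi * shape.area / shape.convex_perimeter ** 2,
        "sphericity": shape.inscribed_radius / max(shape.circumscribed_radius, 1e-12),
        "compactness": 4.0 * math.pi * shape.area / shape.perimeter ** 2,
        "convexity": shape.convex_perimeter / shape.perimeter,
        "eccentricity": shape.minor_axis / major,
        "solidity": shape.area / shape.convex_area,
    }


def shape_metrics_for_mask(label_mask: np.ndarray) -> pd.DataFrame:
    """Shape metrics for every labelled cell; degenerate cells get NaN."""
    rows = {}
    for lab in np.unique(label_mask):
        if lab == 0:
            continue
        try:
            rows[int(lab)] = shape_metrics(CellShape.from_mask(label_mask == lab))
        except ValueError:
            rows[int(lab)] = {k: np.nan for k in SHAPE_METRIC_NAMES}
    return pd.DataFrame.from_dict(rows, orient="index")[SHAPE_METRIC_NAMES]


# ---------------------------------------------------------------------------
# [A] baseline characteristics


def baseline_metrics(matrix: pd.DataFrame, mask: np.ndarray,
                     total_transcripts: Optional[int] = None):
    """Per-cell counts/areas/density plus overall summary.

    Density is total transcripts of the cell divided by its area in pixels^2.
    """
    labels, areas = np.unique(mask[mask > 0], return_counts=True)
    area_of = dict(zip(labels.tolist(), areas.tolist()))
    per_cell = pd.DataFrame(index=matrix.index)
    per_cell["n_transcripts"] = matrix.sum(axis=1)
    per_cell["n_genes"] = (matrix > 0).sum(axis=1)
    per_cell["area"] = [area_of.get(c, 0) for c in matrix.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        per_cell["density"] = np.where(per_cell["area"] > 0,
                                       per_cell["n_transcripts"] / per_cell["area"],
                                       0.0)
    assigned = int(matrix.values.sum())
    overall = {
        "n_cells": int(len(matrix)),
        "total_assigned": assigned,
        "mean_transcripts_per_cell": float(per_cell["n_transcripts"].mean())
        if len(per_cell) else 0.0,
    }
    if total_transcripts:
        overall["proportion_assigned"] = assigned / total_transcripts
    gene_fraction = (matrix > 0).mean(axis=0) if len(matrix) else \
        pd.Series(0.0, index=matrix.columns)
    return per_cell, gene_fraction, overall


# ---------------------------------------------------------------------------
# [B] expression purity


def _decile_sets(counts: pd.Series, fraction: float = 0.10):
    """Top/bottom decile gene sets of one cell, deterministic at ties."""
    k = math.ceil(fraction * len(counts))
    top = sorted(counts.index, key=lambda g: (-counts[g], g))[:k]
    bottom = sorted(counts.index, key=lambda g: (counts[g], g))[:k]
    return set(top), set(bottom)


def _prf(predicted: set, truth: set):
    if not predicted or not truth:
        return 0.0, 0.0, 0.0
    tp = len(predicted & truth)
    prec = tp / len(predicted)
    rec = tp / len(truth)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return prec, rec, f1


def purity_f1(f1_positive: float, f1_negative: float) -> float:
    """Combined purity score from scaled-average positive/negative marker F1."""
    num = 2.0 * (1.0 - f1_negative) * f1_positive
    den = 1.0 - f1_negative + f1_positive
    return 0.0 if den == 0 else num / den


def purity_scores(matrix: pd.DataFrame, types: dict, markers: MarkerSets,
                  fraction: float = 0.10):
    """Per-cell marker precision/recall/F1 and per-type purity F1.

    Each cell's top/bottom expression deciles are compared against its
    type's positive/negative marker sets; per-type average F1 scores combine
    into the purity F1.  Types without markers are excluded.
    """
    rows = []
    for cid in matrix.index:
        t = types.get(cid)
        if t is None or t not in markers.positive:
            continue
        pos_true, neg_true = markers.positive[t], markers.negative[t]
        if not pos_true or not neg_true:
            continue
        top, bottom = _decile_sets(matrix.loc[cid], fraction)
        pp, pr, pf = _prf(top, set(pos_true))
        np_, nr, nf = _prf(bottom, set(neg_true))
        rows.append({"cell_id": cid, "cell_type": t,
                     "precision_pos": pp, "recall_pos": pr, "f1_pos": pf,
                     "precision_neg": np_, "recall_neg": nr, "f1_neg": nf})
    per_cell = pd.DataFrame(rows)
    if per_cell.empty:
        return per_cell, pd.DataFrame()
    per_type = per_cell.groupby("cell_type")[["f1_pos", "f1_neg"]].mean()
    per_type["purity_f1"] = [purity_f1(r.f1_pos, r.f1_neg)
                             for r in per_type.itertuples()]
    return per_cell, per_type


def log_normalise(matrix: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log1p of counts scaled to ``scale`` per cell (library-size normalised)."""
    sums = matrix.sum(axis=1).replace(0, 1)
    return np.log1p(matrix.div(sums, axis=0) * scale)


def concordance_with_reference(matrix: pd.DataFrame, types: dict,
                               profile: ReferenceProfile):
    """Per-type Pearson r of mean log-normalised expression vs the reference,
    plus the r between observed and reference cell-type proportion vectors."""
    common = [g for g in matrix.columns if g in set(profile.genes)]
    if not common:
        raise ValueError("no shared genes with the reference profile")
    logm = log_normalise(matrix[common])
    ref = np.log1p(profile.mean_expression[common])
    per_type = {}
    counts = {}
    for t in profile.cell_types:
        cells = [c for c in matrix.index if types.get(c) == t]
        counts[t] = len(cells)
        if len(cells) < 2:
            per_type[t] = None
            continue
        mean_expr = logm.loc[cells].mean(axis=0).to_numpy()
        r = ref.loc[t].to_numpy()
        if mean_expr.std() == 0 or r.std() == 0:
            per_type[t] = None
            continue
        per_type[t] = float(np.corrcoef(mean_expr, r)[0, 1])
    total = sum(counts.values())
    prop_corr = None
    if total and len(counts) > 1:
        obs = np.array([counts[t] / total for t in profile.cell_types])
        ref_tot = profile.mean_expression.sum(axis=1)
        ref_prop = (ref_tot / ref_tot.sum()).to_numpy()
        if obs.std() > 0 and ref_prop.std() > 0:
            prop_corr = float(np.corrcoef(obs, ref_prop)[0, 1])
    return per_type, prop_corr


def proportion_correlation(p1: dict, p2: dict) -> float:
    """Pearson r between two cell-type proportion maps over shared types."""
    types = sorted(set(p1) & set(p2))
    if len(types) < 2:
        raise ValueError("need at least two shared cell types")
    a = np.array([p1[t] for t in types], float)
    b = np.array([p2[t] for t in types], float)
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# [C] spatial diversity


def shannon_entropy(proportions) -> float:
    p = np.asarray(list(proportions), float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if len(p) else 0.0


def spatial_diversity(cell_table: pd.DataFrame, image_shape: tuple,
                      n_regions: int = 10, min_cells_for_cv: int = 3):
    """Per-region Shannon entropy of cell-type composition and CVs of
    cell-level characteristics, with the entropy-vs-CV Pearson r.

    ``cell_table`` needs columns centroid_row, centroid_col, cell_type, and
    one column per characteristic.  The image is gridded into
    ``n_regions`` x ``n_regions`` squares; cells fall in the region holding
    their centroid.  Regions with fewer than ``min_cells_for_cv`` cells are
    excluded from the CV computation.
    """
    H, W = image_shape
    chars = [c for c in cell_table.columns
             if c not in ("centroid_row", "centroid_col", "cell_type")]
    ri = np.minimum((cell_table["centroid_row"] / H * n_regions).astype(int),
                    n_regions - 1)
    ci = np.minimum((cell_table["centroid_col"] / W * n_regions).astype(int),
                    n_regions - 1)
    region = ri * n_regions + ci
    rows = []
    for reg, grp in cell_table.groupby(region):
        comp = grp["cell_type"].value_counts(normalize=True)
        row = {"region": reg, "n_cells": len(grp),
               "entropy": shannon_entropy(comp.values)}
        for ch in chars:
            vals = grp[ch].to_numpy(float)
            if len(grp) >= min_cells_for_cv and np.nanmean(vals) != 0:
                row[f"cv_{ch}"] = float(np.nanstd(vals) / abs(np.nanmean(vals)))
            else:
                row[f"cv_{ch}"] = np.nan
        rows.append(row)
    regions = pd.DataFrame(rows)
    if len(regions) < 2:
        raise ValueError("need at least two non-empty regions")
    correlations = {}
    for ch in chars:
        sub = regions.dropna(subset=[f"cv_{ch}"])
        if len(sub) < 2 or sub["entropy"].std() == 0 or sub[f"cv_{ch}"].std() == 0:
            correlations[ch] = None
        else:
            correlations[ch] = float(np.corrcoef(sub["entropy"],
                                                 sub[f"cv_{ch}"])[0, 1])
    return regions, correlations


# ---------------------------------------------------------------------------
# [D] neighbour contamination


def neighbour_contamination(centroids_a: np.ndarray, centroids_b: np.ndarray,
                            expr_a: pd.DataFrame, marker_gene: str,
                            distance_bins) -> pd.DataFrame:
    """Fraction of type-A cells expressing a type-B negative marker, grouped
    by distance to the nearest type-B cell."""
    bins = np.asarray(distance_bins, float)
    if not np.all(np.diff(bins) > 0):
        raise ValueError("distance bins must be strictly increasing")
    if len(centroids_a) == 0 or len(centroids_b) == 0:
        raise ValueError("both cell types must be present")
    dist, _ = cKDTree(centroids_b).query(centroids_a)
    expressing = (expr_a[marker_gene] > 0).to_numpy()
    which = np.digitize(dist, bins)
    rows = []
    for b in range(1, len(bins)):
        in_bin = which == b
        rows.append({
            "bin_low": bins[b - 1], "bin_high": bins[b],
            "n_cells": int(in_bin.sum()),
            "fraction_expressing": float(expressing[in_bin].mean())
            if in_bin.any() else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# [E] replicability


def replicability(per_cell_1: pd.DataFrame, types_1: dict,
                  per_cell_2: pd.DataFrame, types_2: dict) -> dict:
    """Pearson r, between two replicates, of per-type means of each baseline
    characteristic and of the cell-type proportion vectors."""
    t1 = pd.Series({c: types_1[c] for c in per_cell_1.index if c in types_1})
    t2 = pd.Series({c: types_2[c] for c in per_cell_2.index if c in types_2})
    shared = sorted(set(t1.unique()) & set(t2.unique()))
    if not shared:
        raise ValueError("replicates share no cell types")
    out = {}
    chars = [c for c in per_cell_1.columns if c in per_cell_2.columns]
    for ch in chars:
        m1 = per_cell_1.loc[t1.index].groupby(t1)[ch].mean().reindex(shared)
        m2 = per_cell_2.loc[t2.index].groupby(t2)[ch].mean().reindex(shared)
        if len(shared) < 2 or m1.std() == 0 or m2.std() == 0:
            out[ch] = None
        else:
            out[ch] = float(np.corrcoef(m1, m2)[0, 1])
    p1 = t1.value_counts(normalize=True).reindex(shared, fill_value=0.0)
    p2 = t2.value_counts(normalize=True).reindex(shared, fill_value=0.0)
    if len(shared) >= 2 and p1.std() > 0 and p2.std() > 0:
        out["type_proportions"] = float(np.corrcoef(p1, p2)[0, 1])
    else:
        out["type_proportions"] = None
    return out
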