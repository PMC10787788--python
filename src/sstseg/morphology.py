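"""Nucleus typing, eccentricity, and per-cell expansion masks.

Each nucleus is typed by Spearman correlation of its in-nucleus expression
vector against the reference profiles.  An ellipse is fitted to the nucleus
mask by second-order image moments; its eccentricity ecc = sqrt(1 - b^2/a^2)
drives the geometry of the cell-calling expansion mask: round cell types are
dilated once with a disc of diameter 20 px, elongated types with a rotated
elliptical kernel whose horizontal/vertical lengths are

    l_h = alpha * ecc * l_t,    l_v = max(l_t - l_h, l_vm)

with defaults alpha = 0.9, l_t = 60 px, l_vm = 3 px.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from .config import ExpansionConfig
from .markers import ReferenceProfile
from .sst_io import ExpressionMap

FALLBACK_TYPE = "unknown_round"


@dataclass
class NucleusSummary:
    cell_id: int
    expression: np.ndarray        # per-gene counts within the nucleus
    eccentricity: float
    orientation: float            # radians of the major axis
    centroid: tuple
    assigned_type: str
    elongated: bool
    correlations: Optional[dict] = None  # type -> Spearman rho, for audit


def nucleus_expression(emap: ExpressionMap, nuclei: np.ndarray) -> pd.DataFrame:
    """Sum the expression map over each nucleus label.

    Returns a cells x genes DataFrame indexed by nucleus label.
    """
    if nuclei.shape != emap.counts.shape[:2]:
        raise ValueError("nuclei mask and expression map shapes disagree")
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    n_genes = emap.counts.shape[2]
    flat = nuclei.ravel()
    out = np.zeros((len(labels), n_genes), dtype=np.int64)
    pos = {lab: i for i, lab in enumerate(labels)}
    for g in range(n_genes):
        sums = np.bincount(flat, weights=emap.counts[:, :, g].ravel(),
                           minlength=int(labels.max()) + 1 if len(labels) else 1)
        for lab in labels:
            out[pos[lab], g] = sums[lab]
    return pd.DataFrame(out, index=labels.tolist(), columns=emap.gene_index)


def assign_type_spearman(expr: pd.DataFrame, profile: ReferenceProfile) -> pd.DataFrame:
    """Assign each nucleus the reference type with the highest Spearman correlation.

    Zero-variance expression vectors get the fallback type ``unknown_round``.
    Ties are broken by cell-type name order.  Returns a DataFrame with the
    per-type correlations and an ``assigned_type`` column.
    """
    common = [g for g in expr.columns if g in set(profile.genes)]
    if not common:
        raise ValueError("no genes shared between expression and reference profile")
    X = expr[common].to_numpy(float)
    P = profile.mean_expression[common].to_numpy(float)
    types = sorted(profile.cell_types)
    order = [profile.cell_types.index(t) for t in types]
    P = P[order]

    # Spearman = Pearson on average ranks
    Pr = np.apply_along_axis(rankdata, 1, P)
    Pr -= Pr.mean(axis=1, keepdims=True)
    p_norm = np.sqrt((Pr ** 2).sum(axis=1))

    rows = []
    assigned = []
    for i in range(X.shape[0]):
        if X[i].std() == 0:
            rows.append({t: np.nan for t in types})
            assigned.append(FALLBACK_TYPE)
            continue
        xr = rankdata(X[i])
        xr -= xr.mean()
        x_norm = np.sqrt((xr ** 2).sum())
        with np.errstate(invalid="ignore"):
            rho = (Pr @ xr) / (p_norm * x_norm)
        rows.append(dict(zip(types, rho)))
        best = int(np.nanargmax(rho))
        assigned.append(types[best])
    out = pd.DataFrame(rows, index=expr.index)
    out["assigned_type"] = assigned
    return out


def nucleus_eccentricity(mask: np.ndarray):
    """Moment-based ellipse fit of a binary nucleus mask.

    Returns (ecc, orientation, a, b) with a >= b the full axis lengths
    (4 * sqrt of the covariance eigenvalues) and ecc = sqrt(1 - b^2/a^2).
    A single-pixel (or otherwise degenerate) mask gives ecc = 0, orientation 0.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty nucleus mask")
    if len(ys) == 1:
        return 0.0, 0.0, 1.0, 1.0
    y = ys - ys.mean()
    x = xs - xs.mean()
    # + 1/12 per axis: variance of the uniform distribution within a pixel
    cov = np.array([[np.mean(x * x) + 1 / 12, np.mean(x * y)],
                    [np.mean(x * y), np.mean(y * y) + 1 / 12]])
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    a = 4.0 * np.sqrt(lam_major)
    b = 4.0 * np.sqrt(lam_minor)
    if a <= 0:
        return 0.0, 0.0, 1.0, 1.0
    ecc = float(np.sqrt(max(0.0, 1.0 - (b / a) ** 2)))
    vy, vx = evecs[1, 1], evecs[0, 1]  # eigenvector of the major axis (x, y) comps
    orientation = float(np.arctan2(vy, vx)) if ecc > 1e-9 else 0.0
    # an axis direction is defined modulo pi; report within (-pi/2, pi/2]
    orientation = (orientation + np.pi / 2) % np.pi - np.pi / 2
    return ecc, orientation, float(a), float(b)


def elongated_kernel_axes(ecc: float, alpha: float = 0.9, l_t: float = 60.0,
                          l_vm: float = 3.0):
    """Horizontal/vertical lengths of the elliptical dilation kernel.

    l_h = alpha * ecc * l_t; l_v = l_t - l_h when that exceeds l_vm, else
    l_vm.  Both floored at 1 px so the kernel stays valid.
    """
    if not (0.0 <= ecc <= 1.0):
        raise ValueError("eccentricity must be within [0, 1]")
    l_h = alpha * ecc * l_t
    l_v = l_t - l_h if (l_t - l_h) > l_vm else l_vm
    return max(l_h, 1.0), max(l_v, 1.0)


def circular_kernel(diameter: int) -> np.ndarray:
    """Disc inscribed in a diameter x diameter window."""
    c = (diameter - 1) / 2.0
    yy, xx = np.mgrid[0:diameter, 0:diameter]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (diameter / 2.0) ** 2


def elliptical_kernel(l_h: float, l_v: float, theta: float) -> np.ndarray:
    """Rotated elliptical structuring element with full axis lengths l_h, l_v."""
    size = int(np.ceil(max(l_h, l_v))) | 1  # odd so the origin is central
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - c, xx - c
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    kern = (u / (l_h / 2.0)) ** 2 + (v / (l_v / 2.0)) ** 2 <= 1.0
    kern[int(c), int(c)] = True  # origin always included
    return kern


def expansion_mask(nucleus: np.ndarray, elongated: bool, ecc: float = 0.0,
                   orientation: float = 0.0,
                   config: ExpansionConfig = ExpansionConfig()) -> np.ndarray:
    """Per-cell expansion mask: one dilation of the nucleus with a disc
    (round types) or a rotated elliptical kernel (elongated types)."""
    nucleus = nucleus.astype(bool)
    if not nucleus.any():
        return nucleus
    if elongated:
        l_h, l_v = elongated_kernel_axes(ecc, config.alpha, config.total_length,
                                         config.min_vertical_length)
        kern = elliptical_kernel(l_h, l_v, orientation)
    else:
        kern = circular_kernel(config.round_kernel_diameter)
    out = ndimage.binary_dilation(nucleus, structure=kern)
    return out | nucleus


def summarize_nuclei(emap: ExpressionMap, nuclei: np.ndarray,
                     profile: ReferenceProfile) -> list:
    """Type every nucleus and fit its ellipse; returns a list of NucleusSummary."""
    expr = nucleus_expression(emap, nuclei)
    corr = assign_type_spearman(expr, profile)
    summaries = []
    for lab in expr.index:
        mask = nuclei == lab
        ecc, theta, _, _ = nucleus_eccentricity(mask)
        ys, xs = np.nonzero(mask)
        atype = corr.loc[lab, "assigned_type"]
        elong = profile.is_elongated(atype) if atype != FALLBACK_TYPE else False
        summaries.append(NucleusSummary(
            cell_id=int(lab),
            expression=expr.loc[lab].to_numpy(),
            eccentricity=ecc,
            orientation=theta,
            centroid=(float(ys.mean()), float(xs.mean())),
            assigned_type=atype,
            elongated=elong,
            correlations={t: corr.loc[lab, t] for t in corr.columns
                          if t != "assigned_type"},
        ))
    return summaries


def summaries_to_csv(summaries: list, path) -> None:
    rows = []
    for s in summaries:
        row = {"cell_id": s.cell_id, "assigned_type": s.assigned_type,
               "eccentricity": s.eccentricity, "orientation": s.orientation,
               "elongated": s.elongated,
               "centroid_row": s.centroid[0], "centroid_col": s.centroid[1]}
        if s.correlations:
            row.update({f"rho_{t}": v for t, v in s.correlations.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
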