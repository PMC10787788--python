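"""Reading, writing, and rasterisation of the pipeline's standard artifacts.

Coordinate convention: 0-based, pixel (i, j) = (row, col) = (y, x); transcript
positions are continuous in pixel units and binned by floor onto half-open
pixel intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

TRANSCRIPT_COLUMNS = ["x", "y", "gene", "qv"]


@dataclass
class ExpressionMap:
    """H x W x n_genes transcript-count tensor on the pixel grid."""

    counts: np.ndarray
    gene_index: list
    pixel_size: float = 1.0  # microns per pixel

    @property
    def shape(self):
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Patch:
    """One cropped window of the expression map and nuclei mask."""

    expression: np.ndarray   # patch x patch x n_genes
    nuclei: np.ndarray       # patch x patch labels
    origin: tuple            # (row, col) of the patch's top-left in the image
    grid: str                # "primary" or "shifted"
    padded: tuple = (0, 0)   # rows, cols of zero padding applied at the edge
    empty_of_nuclei: bool = False

    @property
    def centre(self):
        return (self.origin[0] + self.expression.shape[0] / 2.0,
                self.origin[1] + self.expression.shape[1] / 2.0)


def filter_transcripts(raw: pd.DataFrame, min_qv: float = 20.0,
                       exclude_patterns=("NegPrb", "Blank-")) -> pd.DataFrame:
    """Remove low-quality and control-probe records.

    Records with qv strictly below ``min_qv`` are removed; records without a
    qv value are kept.  Records whose gene name contains any of the
    ``exclude_patterns`` substrings are removed.
    """
    df = raw.copy()
    if "qv" in df.columns:
        qv = pd.to_numeric(df["qv"], errors="coerce")
        df = df[qv.isna() | (qv >= min_qv)]
    names = df["gene"].astype(str)
    for pat in exclude_patterns:
        df = df[~names.str.contains(pat, regex=False)]
        names = df["gene"].astype(str)
    if len(df) == 0:
        logger.warning("transcript filter removed every record")
    return df.reset_index(drop=True)


def build_expression_map(t: pd.DataFrame, height: int, width: int,
                         gene_panel, pixel_size: float = 1.0) -> ExpressionMap:
    """Rasterise a transcript table onto an H x W x n_genes count tensor.

    Positions are floor-binned; records outside [0, H) x [0, W) or with genes
    absent from ``gene_panel`` are dropped, with the counts logged.
    """
    if height <= 0 or width <= 0:
        raise ValueError("map dimensions must be positive")
    gene_panel = list(gene_panel)
    gidx = {g: i for i, g in enumerate(gene_panel)}
    counts = np.zeros((height, width, len(gene_panel)), dtype=np.int32)
    if len(t):
        rows = np.floor(t["y"].to_numpy(float)).astype(int)
        cols = np.floor(t["x"].to_numpy(float)).astype(int)
        genes = t["gene"].to_numpy()
        known = np.fromiter((g in gidx for g in genes), bool, len(genes))
        n_unknown = int((~known).sum())
        if n_unknown:
            logger.info("dropped %d records with genes outside the panel", n_unknown)
        inb = (rows >= 0) & (rows < height) & (cols >= 0) & (cols < width)
        n_oob = int((known & ~inb).sum())
        if n_oob:
            logger.info("dropped %d out-of-bounds records", n_oob)
        keep = known & inb
        gcol = np.fromiter((gidx[g] for g in genes[keep]), int, int(keep.sum()))
        np.add.at(counts, (rows[keep], cols[keep], gcol), 1)
    return ExpressionMap(counts=counts, gene_index=gene_panel, pixel_size=pixel_size)


def _crop(arr: np.ndarray, r0: int, c0: int, size: int):
    """Zero-padded crop of a window that may extend past the array edge."""
    H, W = arr.shape[:2]
    r1, c1 = min(r0 + size, H), min(c0 + size, W)
    out_shape = (size, size) + arr.shape[2:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    out[: r1 - r0, : c1 - c0] = arr[r0:r1, c0:c1]
    return out, (size - (r1 - r0), size - (c1 - c0))


def crop_patches(emap: ExpressionMap, nuclei: np.ndarray, patch: int,
                 grids=("primary", "shifted")) -> list:
    """Tile the map into two half-overlapping square patch grids.

    The primary grid tiles at stride = patch from (0, 0); the shifted grid is
    offset by patch/2 in both axes.  Edge patches are zero-padded to full
    size.  Patches whose nuclei crop has no labels are flagged
    ``empty_of_nuclei`` (they yield no cells).
    """
    H, W = emap.counts.shape[:2]
    if patch > min(H, W):
        raise ValueError("patch size exceeds image dimensions")
    half = patch // 2
    patches = []
    for grid in grids:
        for r0 in (range(0, H, patch) if grid == "primary" else range(half, H, patch)):
            for c0 in (range(0, W, patch) if grid == "primary" else range(half, W, patch)):
                exp, pad = _crop(emap.counts, r0, c0, patch)
                nuc, _ = _crop(nuclei, r0, c0, patch)
                patches.append(Patch(expression=exp, nuclei=nuc, origin=(r0, c0),
                                     grid=grid, padded=pad,
                                     empty_of_nuclei=not (nuc > 0).any()))
    return patches


# ---------------------------------------------------------------------------
# file formats


def write_transcripts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_transcripts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "gene") if c not in df.columns]
    if missing:
        raise ValueError(f"transcript table {path} lacks columns {missing}")
    return df


def write_label_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    dtype = np.uint16 if mask.max() < 2 ** 16 else np.uint32
    tifffile.imwrite(path, mask.astype(dtype))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_gene_cell_matrix(matrix: pd.DataFrame, path) -> None:
    """Write an n_cells x n_genes count matrix.

    ``.csv`` writes a plain CSV with cell ids as the index; ``.mtx`` writes
    MatrixMarket with ``<stem>.cells.tsv`` / ``<stem>.genes.tsv`` sidecars.
    """
    path = Path(path)
    if path.suffix == ".csv":
        matrix.to_csv(path)
    elif path.suffix == ".mtx":
        mmwrite(str(path), sparse.csr_matrix(matrix.values))
        stem = path.with_suffix("")
        pd.Series(matrix.index).to_csv(f"{stem}.cells.tsv", sep="\t",
                                       index=False, header=False)
        pd.Series(matrix.columns).to_csv(f"{stem}.genes.tsv", sep="\t",
                                         index=False, header=False)
    else:
        raise ValueError(f"unsupported matrix format: {path.suffix}")


def read_gene_cell_matrix(path) -> pd.DataFrame:
    path = Path(path)
    try:
        if path.suffix == ".csv":
            df = pd.read_csv(path, index_col=0)
            df.columns = [str(c) for c in df.columns]
            return df
        elif path.suffix == ".mtx":
            mat = np.asarray(mmread(str(path)).todense())
            stem = path.with_suffix("")
            cells = pd.read_csv(f"{stem}.cells.tsv", sep="\t", header=None)[0]
            genes = pd.read_csv(f"{stem}.genes.tsv", sep="\t", header=None)[0]
            return pd.DataFrame(mat, index=cells.tolist(),
                                columns=[str(g) for g in genes.tolist()])
        raise ValueError(f"unsupported matrix format: {path.suffix}")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
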