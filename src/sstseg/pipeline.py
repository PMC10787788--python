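"""High-level orchestration of the segmentation pipeline stages.

Chain: filter transcripts -> rasterise the expression map -> type nuclei and
build expansion masks -> derive training markers -> train the backbone on
primary-grid patches -> predict both patch grids -> merge, refine -> map
transcripts to cells.  The CLI wraps these functions; tests call them
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sst_io
from .config import RunConfig, TrainConfig
from .markers import MarkerSets, ReferenceProfile, derive_markers
from .model import PatchBatch, SmallEncoderDecoder, assemble_segmentation, forward
from .morphology import expansion_mask, summarize_nuclei
from .postprocess import map_transcripts_to_cells, merge_patch_predictions, refine_all
from .train import make_training_stream, prepare_training_patch, train


@dataclass
class PreparedDataset:
    """Everything inference and training need, computed once from the inputs."""

    emap: sst_io.ExpressionMap
    nuclei: np.ndarray
    profile: ReferenceProfile
    summaries: list
    markers: MarkerSets
    expansions_full: dict            # cell_id -> full-image expansion mask
    patches: list                    # both grids
    training_patches: list           # primary grid, non-empty, loss-ready
    transcripts: pd.DataFrame


def prepare(transcripts: pd.DataFrame, nuclei: np.ndarray,
            profile: ReferenceProfile, config: RunConfig) -> PreparedDataset:
    filtered = sst_io.filter_transcripts(transcripts, config.min_qv,
                                         config.exclude_patterns)
    H, W = nuclei.shape
    profile = profile.restrict_genes(profile.genes)
    emap = sst_io.build_expression_map(filtered, H, W, profile.genes,
                                       pixel_size=config.pixel_size)
    summaries = summarize_nuclei(emap, nuclei, profile)
    by_id = {s.cell_id: s for s in summaries}
    expansions_full = {
        s.cell_id: expansion_mask(nuclei == s.cell_id, s.elongated,
                                  s.eccentricity, s.orientation, config.expansion)
        for s in summaries
    }
    markers = derive_markers(profile, config.markers.percentile,
                             config.markers.train_commonality_threshold)
    patches = sst_io.crop_patches(emap, nuclei, config.train.patch_size)
    training_patches = [
        prepare_training_patch(p, by_id, markers, emap.gene_index,
                               config.expansion, expansions_full)
        for p in patches if p.grid == "primary" and not p.empty_of_nuclei
    ]
    return PreparedDataset(emap=emap, nuclei=nuclei, profile=profile,
                           summaries=summaries, markers=markers,
                           expansions_full=expansions_full, patches=patches,
                           training_patches=training_patches,
                           transcripts=filtered)


def train_model(prepared: PreparedDataset, config: TrainConfig,
                width: int = 16):
    """Train the reference backbone on the prepared primary-grid patches."""
    n_in = len(prepared.emap.gene_index) + 1
    model = SmallEncoderDecoder(n_in, width=width, seed=config.rng_seed)
    stream = make_training_stream(prepared.training_patches, config.rng_seed,
                                  config.n_iterations)
    log = train(model, stream, config)
    return model, log


def predict(prepared: PreparedDataset, model) -> np.ndarray:
    """Predict every patch of both grids, merge, and refine."""
    by_id = {s.cell_id: s for s in prepared.summaries}
    predictions = []
    for p in prepared.patches:
        if p.empty_of_nuclei:
            labels = np.zeros(p.nuclei.shape, dtype=np.int32)
        else:
            tp_ids = [int(l) for l in np.unique(p.nuclei) if l > 0]
            batch_nuc = np.stack([p.nuclei == l for l in tp_ids])
            probs = forward(PatchBatch(p.expression, batch_nuc, tp_ids), model)
            labels = assemble_segmentation(probs, tp_ids)
        predictions.append((labels, p.origin, p.grid))
    raw = merge_patch_predictions(predictions, prepared.nuclei.shape)
    return refine_all(raw, prepared.nuclei)


def segment(transcripts: pd.DataFrame, nuclei: np.ndarray,
            profile: ReferenceProfile, config: RunConfig):
    """Full pipeline; returns (cell label mask, gene-cell matrix,
    fraction of transcripts assigned, training log, prepared dataset)."""
    prepared = prepare(transcripts, nuclei, profile, config)
    model, log = train_model(prepared, config.train)
    mask = predict(prepared, model)
    matrix, fraction = map_transcripts_to_cells(prepared.transcripts, mask,
                                                prepared.emap.gene_index)
    return mask, matrix, fraction, log, prepared


def dilation_baseline(nuclei: np.ndarray, radius: int = 1) -> np.ndarray:
    """Nuclei-dilation comparison segmentation: each nucleus grown by
    one pass of a small circular kernel, overlaps going to the lower label."""
    from scipy import ndimage
    out = np.zeros_like(nuclei)
    kern = ndimage.generate_binary_structure(2, 1)
    labels = np.unique(nuclei)
    for lab in labels[labels > 0]:
        grown = ndimage.binary_dilation(nuclei == lab, structure=kern,
                                        iterations=radius)
        out[grown & (out == 0)] = lab
    out[nuclei > 0] = nuclei[nuclei > 0]
    return out


def mean_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-cell intersection-over-union for matching labels."""
    labels = np.unique(truth)
    labels = labels[labels > 0]
    ious = []
    for lab in labels:
        p, t = pred == lab, truth == lab
        union = (p | t).sum()
        ious.append((p & t).sum() / union if union else 0.0)
    return float(np.mean(ious)) if ious else 0.0
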