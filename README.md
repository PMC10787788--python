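# sstseg

Self-supervised, biologically-informed cell segmentation for subcellular
spatial transcriptomics (SST), with a built-in evaluation framework and a
synthetic data generator.

Imaging-based SST platforms (Xenium, CosMx, MERSCOPE, Stereo-seq) record the
position of individual transcripts at sub-micron resolution, but assigning
those transcripts to cells requires a cell segmentation — and nuclear stains
only show the nucleus, not the cell body. `sstseg` trains a small
encoder–decoder network to predict per-cell foreground probabilities directly
from the transcript map, without any manual annotation, by minimising six
loss functions that encode biological expectations:

- **Nuclei encapsulation** `L_ne`: cross-entropy between the patch's nucleus
  mask and the aggregated predicted segmentation — every cell must contain
  its nucleus.
- **Cell calling** `L_cc`: cross-entropy against a per-cell *expansion mask*
  `e_c`, a dilation of the nucleus whose shape depends on the cell type:
  a 20 px disc for round types, a rotated elliptical kernel with axes
  `l_h = α·ecc·l_t`, `l_v = max(l_t − l_h, l_vm)` (α = 0.9, l_t = 60 px,
  l_vm = 3 px) for elongated types, where `ecc = √(1 − b²/a²)` is the
  eccentricity of the moment-fitted nucleus ellipse.
- **Over-segmentation** `L_os`: hinge on
  `Σ_c (p_cyto,c − p_nuc,c)` with `p = Σ_ij σ(q̂·mask − 0.5)` — cytoplasmic
  prediction mass must not exceed nuclear mass.
- **Overlap** `L_ov`: penalises multiple cells claiming the same non-nuclear
  pixel.
- **Positive / negative markers** `L_pos`, `L_neg`: each cell type's top and
  bottom decile genes (by differential reference expression) are rasterised
  into binary maps; the model is rewarded for covering positive-marker
  pixels and penalised on negative-marker pixels.

The total loss is `Σ λ_i L_i` with all λ = 1. Cells are typed by Spearman
correlation of in-nucleus expression against a reference cell-type × gene
profile. Training and inference run on 48×48 patches (two grids offset by
half a patch); predictions are merged, morphologically refined (closing,
nucleus-anchored component selection, hole filling), and transcripts are
assigned by point-in-mask lookup to produce the gene–cell matrix.

Evaluation covers five categories: baseline characteristics (counts, areas,
density = Σnᵢ/A, eight shape metrics including circularity = 4πA/P²_convex
and solidity = A/A_convex), expression purity (marker precision/recall/F1
and the combined purity F1 = 2·(1−F1_neg)·F1_pos / (1−F1_neg+F1_pos)),
spatial diversity (Shannon entropy of regional type composition vs
coefficient-of-variation of cell characteristics), neighbour contamination
(negative-marker expression vs distance to the nearest cell of the marker's
type), and replicability across replicates.

Everything is implemented in NumPy/SciPy — including the network, its He
initialisation, backpropagation, and the Adam optimiser — so the package
runs on a plain CPU with no deep-learning framework.

## Worked example

Simulate a small tissue and run the full pipeline (about one minute on one
CPU core):

```python
from sstseg import pipeline
from sstseg.config import RunConfig, SimConfig, TrainConfig
from sstseg.synthetic import simulate_dataset

cfg = RunConfig()
cfg.sim = SimConfig(rng_seed=11)          # 256×256 px, 50 cells, 3 types
cfg.train = TrainConfig(n_iterations=300, learning_rate=1e-3, rng_seed=0)

ds = simulate_dataset(cfg.sim)
mask, matrix, fraction, log, prepared = pipeline.segment(
    ds.transcripts, ds.nuclei_mask, ds.profile, cfg)

print(f"segmented cells: {len(matrix)}")
print(f"fraction of transcripts assigned: {fraction:.3f}")
print(f"mean IoU vs ground truth: "
      f"{pipeline.mean_iou(mask, ds.truth.cell_mask):.3f}")
print(f"nuclei-dilation baseline IoU: "
      f"{pipeline.mean_iou(pipeline.dilation_baseline(ds.nuclei_mask), ds.truth.cell_mask):.3f}")
correct = sum(s.assigned_type == ds.truth.cell_types[s.cell_id]
              for s in prepared.summaries)
print(f"nucleus typing accuracy: {correct / len(prepared.summaries):.2f}")
print(f"training loss: {log['total'].iloc[0]:.0f} -> {log['total'].iloc[-1]:.0f}")
```

prints (numbers from this exact configuration):

```
segmented cells: 50
fraction of transcripts assigned: 0.621
mean IoU vs ground truth: 0.564
nuclei-dilation baseline IoU: 0.385
nucleus typing accuracy: 1.00
training loss: 5841 -> 2533
```

Every simulated nucleus becomes exactly one connected cell containing it;
the learned segmentation recovers 62% of transcripts and beats the
dilate-the-nucleus baseline by ~0.18 mean IoU after only 300 CPU training
steps. (The defaults in `TrainConfig` — 4000 iterations at learning rate
1e-5 — are the full-scale settings; the example above scales both down for
a quick run.)

The same pipeline is available from the shell:

```bash
sstseg simulate --outdir run --seed 11
sstseg run-all  --outdir run
sstseg evaluate --outdir run
```

Inputs for real data are a transcript table (CSV with columns `x, y, gene,
qv`), a nuclei instance-label mask (TIFF), and a reference cell-type × gene
mean-expression matrix (CSV), plus the list of cell types to treat as
elongated. Transcripts with quality below 20 and control probes
(`NegPrb*`, `Blank-*`) are removed before mapping.

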