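"""Configuration dataclasses shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass
class SimConfig:
    """Parameters of the synthetic subcellular spatial transcriptomics generator.

    Cells are non-overlapping ellipses with concentric elliptical nuclei.
    Per-cell transcript counts are Poisson with mean ``mean_transcripts_per_cell``;
    gene identities follow the cell type's reference profile with a disjoint
    marker-gene block enriched ``marker_enrichment_fold``-fold. Background
    transcripts are uniform in space and gene identity.
    """

    image_height: int = 256
    image_width: int = 256
    n_cell_types: int = 3
    n_genes: int = 30
    n_cells: int = 50
    elongated_type_names: frozenset = frozenset({"type_0"})
    mean_transcripts_per_cell: float = 200.0
    background_noise_rate: float = 0.001  # expected spurious transcripts / pixel
    nucleus_to_cell_area_ratio: float = 0.3
    eccentricity_range_elongated: tuple = (0.85, 0.97)
    eccentricity_range_round: tuple = (0.0, 0.6)
    marker_enrichment_fold: float = 20.0  # contrast of curated marker panels
    transcript_rate_spread: float = 1.5  # fold change in RNA content between adjacent types
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("image_height", "image_width", "n_cell_types", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.mean_transcripts_per_cell < 0 or self.background_noise_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not (0.0 < self.nucleus_to_cell_area_ratio < 1.0):
            raise ValueError("nucleus_to_cell_area_ratio must be in (0, 1)")
        for rng in (self.eccentricity_range_elongated, self.eccentricity_range_round):
            lo, hi = rng
            if not (0.0 <= lo <= hi < 1.0):
                raise ValueError("eccentricity ranges must lie within [0, 1)")
        self.elongated_type_names = frozenset(self.elongated_type_names)


@dataclass
class LossWeights:
    """Weights of the six loss terms; all default to 1."""

    ne: float = 1.0
    cc: float = 1.0
    os: float = 1.0
    ov: float = 1.0
    pos: float = 1.0
    neg: float = 1.0

    def __post_init__(self):
        if any(v < 0 for v in asdict(self).values()):
            raise ValueError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    """Optimisation settings for self-supervised training.

    Defaults: 4000 iterations of Adam at a fixed learning rate of 1e-5
    with betas (0.9, 0.999) and weight decay 1e-4, on 48x48 patches.
    """

    n_iterations: int = 4000
    learning_rate: float = 1e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 1e-4
    patch_size: int = 48
    rng_seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be nonnegative")
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)


@dataclass
class MarkerConfig:
    percentile: float = 0.10
    train_commonality_threshold: float = 1.0 / 3.0
    purity_commonality_threshold: float = 0.25


@dataclass
class ExpansionConfig:
    """Expansion-mask geometry: circular for round types, elliptical for
    elongated types with axes driven by nucleus eccentricity."""

    round_kernel_diameter: int = 20
    alpha: float = 0.9
    total_length: int = 60
    min_vertical_length: int = 3


@dataclass
class RunConfig:
    """Top-level configuration tying pipeline stages together."""

    output_dir: str = "sstseg_run"
    transcripts_path: Optional[str] = None
    nuclei_path: Optional[str] = None
    reference_path: Optional[str] = None
    pixel_size: float = 1.0
    min_qv: float = 20.0
    exclude_patterns: tuple = ("NegPrb", "Blank-")
    elongated_type_names: tuple = ()
    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)

    def __post_init__(self):
        for name in ("sim", "train", "markers", "expansion"):
            val = getattr(self, name)
            if isinstance(val, dict):
                cls = {"sim": SimConfig, "train": TrainConfig,
                       "markers": MarkerConfig, "expansion": ExpansionConfig}[name]
                setattr(self, name, cls(**val))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["elongated_type_names"] = sorted(self.sim.elongated_type_names)
        return d
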