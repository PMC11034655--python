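"""End-to-end triage pipeline on a cohort of slides.

Chains every stage: cohort manifest -> lab-held-out stratified split ->
grid patching with tissue detection and max-severity labelling ->
imbalance-aware patch sampling -> patch classifier training -> whole-slide
inference -> per-category heatmaps -> slide feature vectors -> slide-level
classifier tuned for malignant sensitivity -> test-set evaluation.

The default configuration is desk-scale: 64x64 patches found on a level-3
thumbnail (8x8-pixel grid cells, the conventional cell granularity),
imbalanced sampling with focal loss, forest-90 features and the boosted
slide classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .categories import Category
from .evaluation import ConfusionMatrix, confusion, malignant_sensitivity
from .heatmaps import build_heatmaps
from .patch_model import (
    LossConfig,
    TrainingConfig,
    collect_patch_dataset,
    default_loss_for,
    infer_patches,
    train_patch_classifier,
)
from .patching import GridSpec, TissueParams, build_patch_table, sample_patches
from .slide_classifier import BoostConfig, SlideModel, fit_boosted, predict_slides
from .slide_features import assemble_forest_vector, forest_feature_names
from .slide_io import Manifest, load_annotations, open_slide
from .split import SplitAssignment, split_manifest
from .synthetic import generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_synthetic_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    patch_size: int = 64
    mag_level: int = 3
    sampling_mode: str = "imbalanced"
    max_per_category: int | None = None
    tissue: TissueParams = field(default_factory=TissueParams)
    # the small default MLP needs a larger step size and smaller batches
    # than a pretrained backbone; schedule, momentum and stopping policy
    # are unchanged
    training: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(learning_rate=0.05, batch_size=32)
    )
    loss: LossConfig | None = None  # None: chosen from sampling balance
    boost: BoostConfig = field(default_factory=BoostConfig)
    n_heldout_labs: int = 2
    seed: int = 0

    @property
    def grid(self) -> GridSpec:
        return GridSpec(patch_size=self.patch_size, mag_level=self.mag_level)


@dataclass
class PipelineResult:
    split: SplitAssignment
    history: list[dict]
    features: pd.DataFrame  # one row per slide: split, truth, feature columns
    slide_model: SlideModel
    test_confusion: ConfusionMatrix
    test_accuracy: float
    test_malignant_sensitivity: float


def run_pipeline(manifest: Manifest, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full pipeline on an existing cohort manifest."""
    grid = config.grid
    split = split_manifest(
        manifest, n_heldout_labs=config.n_heldout_labs, seed=config.seed
    )

    slides, patch_tables, truth = {}, {}, {}
    for rec in manifest:
        slide = open_slide(manifest.resolve(rec.image_path))
        ann = load_annotations(manifest.resolve(rec.annotation_path))
        slides[rec.slide_id] = slide
        truth[rec.slide_id] = rec.category
        patch_tables[rec.slide_id] = build_patch_table(
            slide, ann, grid, config.tissue, slide_id=rec.slide_id
        )

    def pooled(split_name: str) -> pd.DataFrame:
        ids = split.slide_ids(split_name)
        return pd.concat([patch_tables[s] for s in ids], ignore_index=True)

    train_sampled = sample_patches(
        pooled("train"), config.sampling_mode, config.max_per_category, seed=config.seed
    )
    valid_sampled = sample_patches(
        pooled("valid"), config.sampling_mode, config.max_per_category,
        seed=config.seed + 1,
    )
    train_set = collect_patch_dataset(slides, train_sampled, config.patch_size)
    valid_set = collect_patch_dataset(slides, valid_sampled, config.patch_size)
    loss_cfg = config.loss or default_loss_for(train_set)
    logger.info(
        "training on %d patches (%s, %s loss)",
        len(train_set), config.sampling_mode, loss_cfg.kind,
    )
    model, history = train_patch_classifier(
        train_set, valid_set, loss_cfg=loss_cfg, train_cfg=config.training
    )

    rows = []
    for rec in manifest:
        table = patch_tables[rec.slide_id]
        probs = infer_patches(model, slides[rec.slide_id], table, config.patch_size)
        dims = (int(table["row"].max()) + 1, int(table["col"].max()) + 1)
        heat = build_heatmaps(probs, dims)
        vec = assemble_forest_vector(heat)
        rows.append(
            {
                "slide_id": rec.slide_id,
                "split": split.assignment[rec.slide_id],
                "truth": rec.category.value,
                **dict(zip(forest_feature_names(), vec)),
            }
        )
    features = pd.DataFrame(rows)

    fcols = forest_feature_names()
    tr = features[features["split"] == "train"]
    va = features[features["split"] == "valid"]
    te = features[features["split"] == "test"]
    slide_model = fit_boosted(
        tr[fcols].to_numpy(),
        tr["truth"],
        cfg=config.boost,
        valid_features=va[fcols].to_numpy(),
        valid_labels=va["truth"],
    )
    pred = predict_slides(slide_model, te[fcols].to_numpy())
    cm = confusion(list(te["truth"]), [p.value for p in pred])
    return PipelineResult(
        split=split,
        history=history,
        features=features,
        slide_model=slide_model,
        test_confusion=cm,
        test_accuracy=cm.accuracy,
        test_malignant_sensitivity=malignant_sensitivity(cm),
    )


def run_synthetic_pipeline(
    out_dir: str | Path,
    n_slides: int = 120,
    n_labs: int = 4,
    size_range: tuple[int, int] = (512, 1024),
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Generate a synthetic cohort and run the full pipeline on it."""
    mix = {c: 0.25 for c in Category}
    manifest = generate_cohort(
        n_slides=n_slides,
        category_mix=mix,
        n_labs=n_labs,
        seed=seed,
        out_dir=out_dir,
        size_range=size_range,
    )
    if config is None:
        config = PipelineConfig(
            seed=seed,
            training=TrainingConfig(learning_rate=0.05, batch_size=32, seed=seed),
            boost=BoostConfig(seed=seed),
        )
    return run_pipeline(manifest, config)
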