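"""Shared fixtures: small synthetic cohorts and pure-texture patch sets."""

from __future__ import annotations

import numpy as np
import pytest

from wsitriage.categories import CATEGORIES, Category
from wsitriage.patch_model import PatchDataset
from wsitriage.raster import rasterize_polygon
from wsitriage.synthetic import (
    LesionSpec,
    SyntheticSlideSpec,
    _draw_tissue_disks,
    generate_cohort,
    generate_slide,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-slide, 4-lab cohort of small slides, generated once per session."""
    out = tmp_path_factory.mktemp("cohort")
    mix = {c: 0.25 for c in Category}
    manifest = generate_cohort(
        12, mix, n_labs=4, seed=7, out_dir=out, size_range=(192, 256)
    )
    return manifest


def make_lesion_slide(
    category: Category,
    seed: int = 0,
    size: int = 320,
    lesion_scale: float = 0.7,
) -> tuple:
    """One slide with a single large lesion of ``category`` (or none).

    The lesion is centred on the largest tissue disk so that pure interior
    patches can be carved out.  Returns ``(pyramid, annotations, spec)``.
    """
    spec = SyntheticSlideSpec(
        width=size, height=size, tissue_blob_count=2, seed=seed,
        slide_id=f"{category.value}_{seed}",
    )
    disks = _draw_tissue_disks(spec, np.random.default_rng(spec.seed))
    if category is not Category.NORMAL:
        cx, cy, r = max(disks, key=lambda d: d[2])
        spec.lesions = [
            LesionSpec(category=category, center=(cx, cy), radius=lesion_scale * (r - 4))
        ]
    pyramid, ann = generate_slide(spec)
    return pyramid, ann, spec


def pure_patches_from_slide(pyramid, ann, category: Category, patch: int = 64,
                            stride: int = 32, limit: int = 60) -> np.ndarray:
    """64x64 patches lying entirely inside the lesion (or tissue, for normal)."""
    h, w = pyramid.level0_height, pyramid.level0_width
    if category is Category.NORMAL:
        # interior of tissue away from the boundary: use the darker-than-white test
        level0 = pyramid.read_region(0, (0, 0), (w, h))
        mask = level0.mean(axis=2) < 235
    else:
        mask = np.zeros((h, w), dtype=bool)
        for p in ann.polygons:
            if p.category is category:
                mask |= rasterize_polygon(p.vertices, (h, w))
    integral = np.pad(mask.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    out = []
    for y in range(0, h - patch, stride):
        for x in range(0, w - patch, stride):
            total = (
                integral[y + patch, x + patch]
                - integral[y, x + patch]
                - integral[y + patch, x]
                + integral[y, x]
            )
            if total == patch * patch:
                out.append(pyramid.read_region(0, (x, y), (patch, patch)))
            if len(out) >= limit:
                return np.stack(out)
    return np.stack(out) if out else np.empty((0, patch, patch, 3), np.uint8)


@pytest.fixture(scope="session")
def pure_patch_dataset() -> PatchDataset:
    """Pure-texture 64x64 patches of all four categories, ~140+ per class."""
    images, labels = [], []
    for rank, cat in enumerate(CATEGORIES):
        collected = 0
        for seed in range(3, 45):
            pyr, ann, _ = make_lesion_slide(cat, seed=seed, size=512, lesion_scale=0.85)
            patches = pure_patches_from_slide(pyr, ann, cat, limit=20)
            images.extend(patches)
            labels.extend([rank] * len(patches))
            collected += len(patches)
            if collected >= 150:
                break
        assert collected >= 100, f"too few pure patches for {cat.value}"
    return PatchDataset(np.stack(images), np.asarray(labels))
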