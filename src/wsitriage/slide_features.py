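"""Slide-level feature extraction from category heatmaps.

Two fixed-length schemes are supported:

* **forest-90** — for each of the malignant, high-grade and low-grade
  heatmaps, at thresholds (0.5, 0.6, 0.7, 0.8, 0.9), two global features:
  ``area_ratio`` (thresholded cells / tissue area) and ``prob_area``
  (probability mass of thresholded cells / tissue area) — 30 values; plus,
  for the 2 largest connected regions of each of the three heatmaps at the
  regional threshold, 10 regional shape/intensity features — 60 values.
  Total 90.

* **boosted** — ``area_ratio`` of the malignant and high-grade heatmaps at
  (0.5, 0.7, 0.9) — 6 global values; plus the 7/5/3/2 largest regions of
  the malignant/high-grade/low-grade/normal heatmaps with a per-category
  subset of 12 regional features (12/11/9/5 enabled), totalling 182.

Regions are 8-connected components; missing regions contribute zeros so
vector lengths are constant.  Region intensity is the underlying
probability grid of the same category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .categories import Category
from .heatmaps import CategoryHeatmaps, threshold_heatmap

__all__ = [
    "Region",
    "extract_regions",
    "global_features_forest",
    "region_features_forest",
    "assemble_forest_vector",
    "global_features_boosted",
    "assemble_boosted_vector",
    "forest_feature_names",
    "boosted_feature_names",
    "FOREST_THRESHOLDS",
    "BOOSTED_THRESHOLDS",
    "REGIONAL_THRESHOLD",
]

FOREST_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)
BOOSTED_THRESHOLDS = (0.5, 0.7, 0.9)
#: Threshold defining the binary mask on which regions are extracted.
REGIONAL_THRESHOLD = 0.5

FOREST_HEATMAPS = (Category.MALIGNANT, Category.HIGH_GRADE, Category.LOW_GRADE)
BOOSTED_GLOBAL_HEATMAPS = (Category.MALIGNANT, Category.HIGH_GRADE)
#: Largest-region counts per heatmap for the boosted scheme.
BOOSTED_REGION_COUNTS = {
    Category.MALIGNANT: 7,
    Category.HIGH_GRADE: 5,
    Category.LOW_GRADE: 3,
    Category.NORMAL: 2,
}

FOREST_REGION_FEATURES = (
    "area",
    "eccentricity",
    "extent",
    "bbox_area",
    "major_axis_length",
    "max_intensity",
    "mean_intensity",
    "min_intensity",
    "bbox_aspect_ratio",
    "solidity",
)

BOOSTED_REGION_FEATURES = (
    "area",
    "bbox_area",
    "major_axis_length",
    "max_intensity",
    "mean_intensity",
    "min_intensity",
    "convex_area",
    "filled_area",
    "minor_axis_length",
    "equivalent_diameter",
    "euler_number",
    "perimeter",
)

#: Enabled regional features per heatmap category for the boosted scheme.
BOOSTED_FEATURE_MASKS: dict[Category, tuple[str, ...]] = {
    Category.MALIGNANT: BOOSTED_REGION_FEATURES,
    Category.HIGH_GRADE: tuple(
        f for f in BOOSTED_REGION_FEATURES if f != "min_intensity"
    ),
    Category.LOW_GRADE: (
        "bbox_area",
        "major_axis_length",
        "max_intensity",
        "mean_intensity",
        "min_intensity",
        "convex_area",
        "filled_area",
        "minor_axis_length",
        "euler_number",
    ),
    Category.NORMAL: (
        "bbox_area",
        "major_axis_length",
        "mean_intensity",
        "filled_area",
        "minor_axis_length",
    ),
}


@dataclass
class Region:
    """One 8-connected component of a thresholded heatmap."""

    pixel_count: int
    seed_index: int  # row-major index of the topmost-leftmost cell
    props: object  # skimage RegionProperties with intensity image

    def feature(self, name: str) -> float:
        p = self.props
        if name == "bbox_aspect_ratio":
            minr, minc, maxr, maxc = p.bbox
            height = maxr - minr
            return (maxc - minc) / height if height else 0.0
        attr = {
            "area": "area",
            "eccentricity": "eccentricity",
            "extent": "extent",
            "bbox_area": "area_bbox",
            "major_axis_length": "axis_major_length",
            "minor_axis_length": "axis_minor_length",
            "max_intensity": "intensity_max",
            "mean_intensity": "intensity_mean",
            "min_intensity": "intensity_min",
            "solidity": "solidity",
            "convex_area": "area_convex",
            "filled_area": "area_filled",
            "equivalent_diameter": "equivalent_diameter_area",
            "euler_number": "euler_number",
            "perimeter": "perimeter",
        }[name]
        return float(np.asarray(getattr(p, attr)).item())


def extract_regions(
    binary: np.ndarray, intensity: np.ndarray, k: int | None = None
) -> list[Region]:
    """The ``k`` largest 8-connected regions of ``binary`` (all if None).

    Sorted by pixel count descending; ties broken by the row-major position
    of each region's topmost-leftmost cell.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != np.asarray(intensity).shape:
        raise ValueError("binary and intensity grids must share a shape")
    labels = cc_label(binary, connectivity=2)
    if labels.max() == 0:
        return []
    props = regionprops(labels, intensity_image=np.asarray(intensity, dtype=float))
    flat = labels.ravel()
    regions = []
    for p in props:
        seed = int(np.flatnonzero(flat == p.label)[0])
        regions.append(Region(pixel_count=int(p.area), seed_index=seed, props=p))
    regions.sort(key=lambda r: (-r.pixel_count, r.seed_index))
    return regions if k is None else regions[:k]


def _check_tissue(h: CategoryHeatmaps) -> None:
    if h.tissue_area == 0:
        raise ValueError("slide has no tissue cells")


def global_features_forest(h: CategoryHeatmaps) -> np.ndarray:
    """30 global features: (area_ratio, prob_area) per heatmap x threshold."""
    _check_tissue(h)
    out = []
    for cat in FOREST_HEATMAPS:
        grid = h.grids[cat]
        for t in FOREST_THRESHOLDS:
            mask = threshold_heatmap(grid, t)
            out.append(mask.sum() / h.tissue_area)
            out.append(grid[mask].sum() / h.tissue_area)
    return np.asarray(out)


def region_features_forest(region: Region) -> np.ndarray:
    """The 10 forest-scheme regional features in fixed order."""
    return np.asarray([region.feature(f) for f in FOREST_REGION_FEATURES])


def assemble_forest_vector(
    h: CategoryHeatmaps, regional_threshold: float = REGIONAL_THRESHOLD
) -> np.ndarray:
    """90-dimensional slide feature vector (30 global + 3 x 2 x 10 regional)."""
    parts = [global_features_forest(h)]
    for cat in FOREST_HEATMAPS:
        grid = h.grids[cat]
        regions = extract_regions(threshold_heatmap(grid, regional_threshold), grid, k=2)
        for slot in range(2):
            if slot < len(regions):
                parts.append(region_features_forest(regions[slot]))
            else:
                parts.append(np.zeros(len(FOREST_REGION_FEATURES)))
    return np.concatenate(parts)


def global_features_boosted(h: CategoryHeatmaps) -> np.ndarray:
    """6 global features: area_ratio of malignant/high-grade at 3 thresholds."""
    _check_tissue(h)
    out = []
    for cat in BOOSTED_GLOBAL_HEATMAPS:
        grid = h.grids[cat]
        for t in BOOSTED_THRESHOLDS:
            out.append(threshold_heatmap(grid, t).sum() / h.tissue_area)
    return np.asarray(out)


def assemble_boosted_vector(
    h: CategoryHeatmaps, regional_threshold: float = REGIONAL_THRESHOLD
) -> np.ndarray:
    """182-dimensional boosted-scheme vector (6 global + masked regional)."""
    parts = [global_features_boosted(h)]
    for cat, n_regions in BOOSTED_REGION_COUNTS.items():
        grid = h.grids[cat]
        enabled = BOOSTED_FEATURE_MASKS[cat]
        regions = extract_regions(
            threshold_heatmap(grid, regional_threshold), grid, k=n_regions
        )
        for slot in range(n_regions):
            if slot < len(regions):
                parts.append(
                    np.asarray([regions[slot].feature(f) for f in enabled])
                )
            else:
                parts.append(np.zeros(len(enabled)))
    return np.concatenate(parts)


def forest_feature_names() -> list[str]:
    names = []
    for cat in FOREST_HEATMAPS:
        for t in FOREST_THRESHOLDS:
            names.append(f"{cat.value}_t{t}_area_ratio")
            names.append(f"{cat.value}_t{t}_prob_area")
    for cat in FOREST_HEATMAPS:
        for slot in range(2):
            for f in FOREST_REGION_FEATURES:
                names.append(f"{cat.value}_r{slot}_{f}")
    return names


def boosted_feature_names() -> list[str]:
    names = []
    for cat in BOOSTED_GLOBAL_HEATMAPS:
        for t in BOOSTED_THRESHOLDS:
            names.append(f"{cat.value}_t{t}_area_ratio")
    for cat, n_regions in BOOSTED_REGION_COUNTS.items():
        for slot in range(n_regions):
            for f in BOOSTED_FEATURE_MASKS[cat]:
                names.append(f"{cat.value}_r{slot}_{f}")
    return names
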