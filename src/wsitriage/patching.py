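"""Grid patch finding, tissue detection, max-severity labelling and sampling.

Patches are fixed-size squares on a non-overlapping grid anchored at the
slide's top-left corner.  The grid is found on a thumbnail at ``mag_level``
``m``: a patch of ``P`` level-0 pixels occupies a cell of ``c = P / 2**m``
thumbnail pixels, and thumbnail coordinates multiplied by ``2**m`` give the
level-0 patch origin.  With the conventional ``P=256, m=5`` a cell is 8x8
thumbnail pixels and each thumbnail pixel stands for a 32x32 = 1024 pixel
level-0 block.

Tissue detection and labelling are deliberately conservative: a patch
counts as tissue if even one of its thumbnail pixels is tissue, and a patch
is labelled with the most severe category whose annotation polygon touches
any of its pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .categories import CATEGORIES, Category
from .raster import rasterize_polygon
from .slide_io import AnnotationSet, SlidePyramid

__all__ = [
    "GridSpec",
    "PatchCoord",
    "PatchRecord",
    "TissueParams",
    "find_grid_patches",
    "detect_tissue",
    "label_patches",
    "build_patch_table",
    "sample_patches",
    "export_patches",
]

logger = logging.getLogger(__name__)

PATCH_COLUMNS = ("slide_id", "row", "col", "x0", "y0", "is_tissue", "label")


@dataclass(frozen=True)
class GridSpec:
    """Patch grid geometry: level-0 patch size and thumbnail mag level."""

    patch_size: int = 256
    mag_level: int = 5

    def __post_init__(self):
        if self.patch_size % 2**self.mag_level:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2**{self.mag_level}"
            )
        if self.cell < 1:
            raise ValueError("grid cell smaller than one thumbnail pixel")

    @property
    def cell(self) -> int:
        """Cell side in thumbnail pixels."""
        return self.patch_size // 2**self.mag_level


@dataclass(frozen=True)
class PatchCoord:
    """Grid cell with level-0 top-left corner ``(x0, y0)``."""

    row: int
    col: int
    x0: int
    y0: int


@dataclass(frozen=True)
class PatchRecord:
    coord: PatchCoord
    is_tissue: bool
    label: Category | None

    def __post_init__(self):
        if self.is_tissue != (self.label is not None):
            raise ValueError("label must be set exactly for tissue patches")


@dataclass(frozen=True)
class TissueParams:
    """Pixel-level tissue test thresholds.

    A pixel is tissue when its luminance falls below ``luminance_max`` of
    full white or its HSV saturation exceeds ``saturation_min``; H&E
    background is near-white (high luminance, low saturation).
    """

    luminance_max: float = 0.88
    saturation_min: float = 0.07

    def __post_init__(self):
        for v in (self.luminance_max, self.saturation_min):
            if not 0.0 < v < 1.0:
                raise ValueError("tissue thresholds must be in (0, 1)")


def find_grid_patches(
    thumbnail_shape: tuple[int, int],
    grid: GridSpec,
    level0_dims: tuple[int, int] | None = None,
) -> list[PatchCoord]:
    """Enumerate full grid cells row-major from the top-left corner.

    ``thumbnail_shape`` is ``(height, width)`` in thumbnail pixels.  Partial
    cells at the right/bottom edge are dropped.  When ``level0_dims=(W, H)``
    is given, cells whose level-0 patch would cross the slide boundary are
    also dropped (the last thumbnail pixel may cover a partial level-0
    block when dimensions are not multiples of ``2**mag_level``).
    """
    h, w = thumbnail_shape[:2]
    c = grid.cell
    n_rows, n_cols = h // c, w // c
    if level0_dims is not None:
        w0, h0 = level0_dims
        n_rows = min(n_rows, h0 // grid.patch_size)
        n_cols = min(n_cols, w0 // grid.patch_size)
    coords = []
    for row in range(n_rows):
        for col in range(n_cols):
            coords.append(
                PatchCoord(
                    row=row,
                    col=col,
                    x0=col * grid.patch_size,
                    y0=row * grid.patch_size,
                )
            )
    return coords


def tissue_pixel_mask(thumbnail: np.ndarray, params: TissueParams) -> np.ndarray:
    """Boolean per-pixel tissue mask of an RGB thumbnail."""
    img = np.asarray(thumbnail, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("thumbnail must be an RGB image")
    if thumbnail.dtype == np.uint8:
        img = img / 255.0
    luminance = img @ np.array([0.299, 0.587, 0.114])
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return (luminance < params.luminance_max) | (saturation > params.saturation_min)


def detect_tissue(
    thumbnail: np.ndarray,
    coords: list[PatchCoord],
    grid: GridSpec,
    params: TissueParams = TissueParams(),
) -> list[bool]:
    """A patch is tissue iff at least one of its thumbnail pixels is tissue."""
    mask = tissue_pixel_mask(thumbnail, params)
    c = grid.cell
    return [
        bool(mask[p.row * c : (p.row + 1) * c, p.col * c : (p.col + 1) * c].any())
        for p in coords
    ]


def _severity_grid(
    annotations: AnnotationSet, shape: tuple[int, int], scale: float
) -> np.ndarray:
    """Max polygon severity per pixel (0 = no polygon / normal)."""
    sev = np.zeros(shape, dtype=np.int8)
    for poly in annotations.polygons:
        mask = rasterize_polygon(poly.vertices * scale, shape)
        rank = poly.category.severity_rank
        np.maximum(sev, np.where(mask, np.int8(rank), np.int8(0)), out=sev)
    return sev


def label_patches(
    coords: list[PatchCoord],
    tissue_flags: list[bool],
    annotations: AnnotationSet,
    grid: GridSpec,
    thumbnail_shape: tuple[int, int],
    exact_level0: bool = False,
    slide_dims: tuple[int, int] | None = None,
) -> list[PatchRecord]:
    """Label each tissue patch with the most severe overlapping category.

    By default polygon overlap is evaluated at thumbnail resolution (the
    grid the patches were found on); ``exact_level0=True`` rasterizes the
    polygons at level 0 instead (``slide_dims=(width, height)`` required),
    which is exact but only practical for small slides.
    """
    if len(coords) != len(tissue_flags):
        raise ValueError("coords and tissue_flags lengths differ")
    if exact_level0:
        if slide_dims is None:
            raise ValueError("slide_dims required for exact_level0 labelling")
        w0, h0 = slide_dims
        sev = _severity_grid(annotations, (h0, w0), scale=1.0)
        cell = grid.patch_size
    else:
        sev = _severity_grid(
            annotations, thumbnail_shape[:2], scale=1.0 / 2**grid.mag_level
        )
        cell = grid.cell

    records = []
    for coord, is_tissue in zip(coords, tissue_flags):
        if not is_tissue:
            records.append(PatchRecord(coord, False, None))
            continue
        block = sev[
            coord.row * cell : (coord.row + 1) * cell,
            coord.col * cell : (coord.col + 1) * cell,
        ]
        rank = int(block.max()) if block.size else 0
        records.append(PatchRecord(coord, True, CATEGORIES[rank]))
    return records


def build_patch_table(
    slide: SlidePyramid,
    annotations: AnnotationSet,
    grid: GridSpec,
    tissue_params: TissueParams = TissueParams(),
    slide_id: str | None = None,
) -> pd.DataFrame:
    """Index one slide: grid, tissue flags and labels as a dataframe."""
    from .slide_io import make_thumbnail

    thumb = make_thumbnail(slide, grid.mag_level)
    coords = find_grid_patches(
        thumb.shape[:2], grid, level0_dims=(slide.level0_width, slide.level0_height)
    )
    flags = detect_tissue(thumb, coords, grid, tissue_params)
    records = label_patches(coords, flags, annotations, grid, thumb.shape[:2])
    sid = slide_id or slide.slide_id or ""
    return pd.DataFrame(
        [
            {
                "slide_id": sid,
                "row": r.coord.row,
                "col": r.coord.col,
                "x0": r.coord.x0,
                "y0": r.coord.y0,
                "is_tissue": r.is_tissue,
                "label": r.label.value if r.label else "",
            }
            for r in records
        ],
        columns=list(PATCH_COLUMNS),
    )


def sample_patches(
    patch_table: pd.DataFrame,
    mode: str = "imbalanced",
    max_per_category: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample training patches from a pooled tissue-patch table.

    ``balanced``: equal counts per category, the minimum category count
    (optionally capped).  ``imbalanced``: keep every malignant patch, an
    equal number of randomly chosen normal patches, and all low/high grade
    patches; this biases training toward malignant sensitivity.
    """
    df = patch_table[patch_table["is_tissue"]].copy()
    rng = np.random.default_rng(seed)
    counts = {c.value: int((df["label"] == c.value).sum()) for c in CATEGORIES}

    if mode == "balanced":
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValueError(f"balanced sampling with empty categories: {empty}")
        take = min(counts.values())
        if max_per_category is not None:
            take = min(take, max_per_category)
        quota = {c: take for c in counts}
    elif mode == "imbalanced":
        n_mal = counts[Category.MALIGNANT.value]
        quota = dict(counts)
        if n_mal > 0:
            quota[Category.NORMAL.value] = min(counts[Category.NORMAL.value], n_mal)
        else:
            logger.warning("no malignant patches; keeping all normal patches")
        if max_per_category is not None:
            quota = {c: min(n, max_per_category) for c, n in quota.items()}
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")

    parts = []
    for cat, take in quota.items():
        sub = df[df["label"] == cat]
        if take < len(sub):
            idx = rng.choice(len(sub), size=take, replace=False)
            sub = sub.iloc[np.sort(idx)]
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def export_patches(
    slide: SlidePyramid,
    records: pd.DataFrame,
    out_dir: str | Path,
    patch_size: int,
) -> list[Path]:
    """Write sampled patches as PNGs under ``out_dir/<category>/``.

    Filenames encode slide id, level-0 origin and patch size, so re-export
    overwrites byte-identical files.
    """
    out_dir = Path(out_dir)
    paths = []
    for row in records.itertuples():
        tile = slide.read_region(0, (int(row.x0), int(row.y0)), (patch_size, patch_size))
        cat_dir = out_dir / str(row.label)
        cat_dir.mkdir(parents=True, exist_ok=True)
        name = f"{row.slide_id}_x{int(row.x0)}_y{int(row.y0)}_p{patch_size}.png"
        path = cat_dir / name
        Image.fromarray(tile).save(path)
        paths.append(path)
    return paths
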