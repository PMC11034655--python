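"""Reading and writing slides, annotations and cohort manifests.

A whole-slide image (WSI) is stored as a multi-resolution pyramid: level 0
is the full-resolution scan and each level above halves both dimensions
(level ``L`` has dimensions ``ceil(dim0 / 2**L)``).  Two on-disk formats
are supported:

* a pyramidal TIFF with one page per level, and
* a directory fixture format (``meta.json`` plus one PNG per level), which
  is what the synthetic cohort generator writes.

All coordinates are 0-based ``(x=column, y=row)`` in half-open intervals;
annotation polygon vertices are always level-0 pixel coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .categories import Category, SubCategory

__all__ = [
    "SlidePyramid",
    "ArraySlidePyramid",
    "open_slide",
    "make_thumbnail",
    "build_pyramid_levels",
    "write_slide_dir",
    "write_pyramidal_tiff",
    "PolygonAnnotation",
    "AnnotationSet",
    "load_annotations",
    "write_annotations",
    "SlideRecord",
    "Manifest",
    "load_manifest",
    "write_manifest",
]

DEFAULT_MPP = 0.25  # microns per level-0 pixel at 40x by convention


def level_dims(level0_dims: tuple[int, int], level: int) -> tuple[int, int]:
    """Dimensions ``(width, height)`` of pyramid level ``level``."""
    w, h = level0_dims
    return (math.ceil(w / 2**level), math.ceil(h / 2**level))


class SlidePyramid:
    """Random-access multi-resolution slide.

    Subclasses provide ``_level_array(level)`` returning the full image of a
    level as a ``(H, W, 3) uint8`` array.
    """

    level0_width: int
    level0_height: int
    n_levels: int
    mpp_level0: float
    slide_id: str | None

    def level_dimensions(self, level: int) -> tuple[int, int]:
        """``(width, height)`` of ``level``; errors if out of range."""
        self._check_level(level)
        return level_dims((self.level0_width, self.level0_height), level)

    def read_region(
        self, level: int, origin: tuple[int, int], size: tuple[int, int]
    ) -> np.ndarray:
        """Read an RGB tile: ``origin=(x, y)`` and ``size=(w, h)`` at ``level``."""
        self._check_level(level)
        x, y = origin
        w, h = size
        lw, lh = self.level_dimensions(level)
        if w <= 0 or h <= 0:
            raise ValueError(f"non-positive region size {size}")
        if x < 0 or y < 0 or x + w > lw or y + h > lh:
            raise ValueError(
                f"region {origin}+{size} outside level-{level} bounds {(lw, lh)}"
            )
        return self._level_array(level)[y : y + h, x : x + w]

    def _level_array(self, level: int) -> np.ndarray:
        raise NotImplementedError

    def _check_level(self, level: int) -> None:
        if not 0 <= level < self.n_levels:
            raise ValueError(f"level {level} out of range [0, {self.n_levels})")


class ArraySlidePyramid(SlidePyramid):
    """In-memory pyramid backed by a list of level arrays."""

    def __init__(
        self,
        levels: list[np.ndarray],
        mpp_level0: float = DEFAULT_MPP,
        slide_id: str | None = None,
    ):
        if not levels:
            raise ValueError("pyramid needs at least one level")
        base = levels[0]
        if base.ndim != 3 or base.shape[2] != 3:
            raise ValueError("levels must be (H, W, 3) RGB arrays")
        self.level0_height, self.level0_width = base.shape[:2]
        self.n_levels = len(levels)
        self.mpp_level0 = mpp_level0
        self.slide_id = slide_id
        for lv, arr in enumerate(levels):
            expect = level_dims((self.level0_width, self.level0_height), lv)
            if (arr.shape[1], arr.shape[0]) != expect:
                raise ValueError(
                    f"level {lv} has dims {(arr.shape[1], arr.shape[0])}, "
                    f"expected {expect}"
                )
        self._levels = [np.ascontiguousarray(a, dtype=np.uint8) for a in levels]

    def _level_array(self, level: int) -> np.ndarray:
        return self._levels[level]


def build_pyramid_levels(level0: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Build pyramid levels from a base image by repeated 2x2 mean pooling.

    Odd dimensions are edge-padded before pooling so level ``L`` dimensions
    are ``ceil(dim0 / 2**L)``.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [np.asarray(level0, dtype=np.uint8)]
    cur = np.asarray(level0, dtype=np.float64)
    for _ in range(1, n_levels):
        h, w = cur.shape[:2]
        if h % 2 or w % 2:
            cur = np.pad(
                cur, ((0, h % 2), (0, w % 2), (0, 0)), mode="edge"
            )
            h, w = cur.shape[:2]
        cur = cur.reshape(h // 2, 2, w // 2, 2, 3).mean(axis=(1, 3))
        levels.append(np.clip(np.round(cur), 0, 255).astype(np.uint8))
    return levels


def write_slide_dir(
    levels: list[np.ndarray],
    out_dir: str | Path,
    mpp_level0: float = DEFAULT_MPP,
    slide_id: str | None = None,
) -> Path:
    """Write the directory fixture format (meta.json + level_##.png)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "wsitriage-slide-dir",
        "level0_width": int(levels[0].shape[1]),
        "level0_height": int(levels[0].shape[0]),
        "n_levels": len(levels),
        "mpp_level0": mpp_level0,
        "slide_id": slide_id,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    for lv, arr in enumerate(levels):
        Image.fromarray(arr).save(out_dir / f"level_{lv:02d}.png")
    return out_dir


def write_pyramidal_tiff(
    levels: list[np.ndarray], path: str | Path, mpp_level0: float = DEFAULT_MPP
) -> Path:
    """Write the pyramid as a multi-page TIFF (page per level)."""
    path = Path(path)
    res = 10_000 / mpp_level0  # pixels per cm
    with tifffile.TiffWriter(path) as tw:
        for lv, arr in enumerate(levels):
            tw.write(
                arr,
                photometric="rgb",
                resolution=(res / 2**lv, res / 2**lv),
                resolutionunit="CENTIMETER",
                description="wsitriage pyramid" if lv == 0 else None,
            )
    return path


def open_slide(path: str | Path) -> SlidePyramid:
    """Open a pyramidal TIFF file or a slide fixture directory."""
    path = Path(path)
    if path.is_dir():
        return _open_slide_dir(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arrays = [page.asarray() for page in tf.pages]
    except Exception as exc:  # truncated / non-TIFF input
        raise ValueError(f"unreadable slide file {path}: {exc}") from exc
    arrays = [a for a in arrays if a.ndim == 3]
    if not arrays:
        raise ValueError(f"{path} contains no RGB pages")
    return ArraySlidePyramid(arrays, slide_id=path.stem)


def _open_slide_dir(path: Path) -> SlidePyramid:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{path} is not a slide directory (missing meta.json)")
    meta = json.loads(meta_path.read_text())
    levels = []
    for lv in range(meta["n_levels"]):
        f = path / f"level_{lv:02d}.png"
        if not f.exists():
            raise ValueError(f"{path} missing pyramid level {lv}")
        levels.append(np.asarray(Image.open(f).convert("RGB")))
    pyr = ArraySlidePyramid(
        levels,
        mpp_level0=meta.get("mpp_level0", DEFAULT_MPP),
        slide_id=meta.get("slide_id") or path.name,
    )
    if (pyr.level0_width, pyr.level0_height) != (
        meta["level0_width"],
        meta["level0_height"],
    ):
        raise ValueError(f"{path}: meta.json dimensions disagree with level 0")
    return pyr


def make_thumbnail(slide: SlidePyramid, mag_level: int) -> np.ndarray:
    """Whole-slide image at ``mag_level``: dims are ``ceil(dim0 / 2**mag_level)``.

    Thumbnail pixel ``(i, j)`` summarizes the ``2**m x 2**m`` level-0 block
    whose top-left corner is ``(i * 2**m, j * 2**m)``.
    """
    if not 0 <= mag_level < slide.n_levels:
        raise ValueError(
            f"mag_level {mag_level} out of range [0, {slide.n_levels})"
        )
    w, h = slide.level_dimensions(mag_level)
    return slide.read_region(mag_level, (0, 0), (w, h))


# ---------------------------------------------------------------------------
# Annotations


@dataclass(frozen=True)
class PolygonAnnotation:
    """One annotated lesion region in level-0 pixel coordinates."""

    vertices: np.ndarray  # (N, 2) float, columns (x, y)
    category: Category
    subcategory: SubCategory

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)


@dataclass
class AnnotationSet:
    """All polygon annotations of one slide plus its slide-level label."""

    polygons: list[PolygonAnnotation]
    slide_label: Category
    slide_sublabel: SubCategory

    def __post_init__(self):
        if self.slide_label is not Category.NORMAL and not self.polygons:
            raise ValueError(
                f"slide labelled {self.slide_label.value} must have >= 1 polygon"
            )

    def validate_bounds(self, width: int, height: int) -> None:
        for p in self.polygons:
            x, y = p.vertices[:, 0], p.vertices[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > width or y.max() > height:
                raise ValueError("annotation polygon outside slide bounds")


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load the per-slide annotation JSON."""
    data = json.loads(Path(path).read_text())
    polys = [
        PolygonAnnotation(
            vertices=np.asarray(p["vertices"], dtype=float),
            category=Category.parse(p["category"]),
            subcategory=SubCategory.parse(p["subcategory"]),
        )
        for p in data.get("polygons", [])
    ]
    return AnnotationSet(
        polygons=polys,
        slide_label=Category.parse(data["slide_label"]),
        slide_sublabel=SubCategory.parse(data["slide_sublabel"]),
    )


def write_annotations(ann: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "slide_label": ann.slide_label.value,
        "slide_sublabel": ann.slide_sublabel.value,
        "polygons": [
            {
                "category": p.category.value,
                "subcategory": p.subcategory.value,
                "vertices": [[float(x), float(y)] for x, y in p.vertices],
            }
            for p in ann.polygons
        ],
    }
    path.write_text(json.dumps(data, indent=1))
    return path


# ---------------------------------------------------------------------------
# Cohort manifest

MANIFEST_COLUMNS = (
    "slide_id",
    "lab_id",
    "category",
    "subcategory",
    "image_path",
    "annotation_path",
)


@dataclass(frozen=True)
class SlideRecord:
    slide_id: str
    lab_id: int
    category: Category
    subcategory: SubCategory
    image_path: str
    annotation_path: str

    def __post_init__(self):
        if not 1 <= self.lab_id <= 8:
            raise ValueError(f"lab_id {self.lab_id} outside 1..8")


@dataclass
class Manifest:
    """Cohort manifest: one record per slide."""

    records: list[SlideRecord]
    root: Path | None = None  # paths in records are relative to this

    def __post_init__(self):
        ids = [r.slide_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate slide_id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lab_ids(self) -> list[int]:
        return sorted({r.lab_id for r in self.records})

    def resolve(self, rel: str) -> Path:
        return (self.root / rel) if self.root is not None else Path(rel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slide_id": r.slide_id,
                    "lab_id": r.lab_id,
                    "category": r.category.value,
                    "subcategory": r.subcategory.value,
                    "image_path": r.image_path,
                    "annotation_path": r.annotation_path,
                }
                for r in self.records
            ],
            columns=list(MANIFEST_COLUMNS),
        )


def load_manifest(path: str | Path) -> Manifest:
    """Load a cohort manifest CSV and validate it."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"slide_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = [
        SlideRecord(
            slide_id=str(row.slide_id),
            lab_id=int(row.lab_id),
            category=Category.parse(row.category),
            subcategory=SubCategory.parse(row.subcategory),
            image_path=str(row.image_path),
            annotation_path=str(row.annotation_path),
        )
        for row in df.itertuples()
    ]
    return Manifest(records=records, root=path.parent)


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False)
    return path
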