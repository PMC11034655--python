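"""Deterministic synthetic cohorts for exercising the full triage pipeline.

Real cervical H&E slides are gigapixel scans with near-white background and
pink/purple tissue; lesions of the four diagnostic categories differ in
stain uptake and nuclear density.  The generator emulates exactly the
statistics the pipeline relies on and nothing more:

* near-white background (all channels >= 0.92 of full scale),
* tissue blobs with an H&E-like base colour and scattered dark "nuclei",
* lesion regions painted inside tissue from polygon outlines, with a
  distinct (base colour, nucleus density) signature per category so that a
  very small classifier can separate them,
* a small deterministic per-lab RGB stain shift (eight staining protocols),
* polygon annotations that exactly delimit the painted regions (an optional
  jitter mode erodes/dilates them to mimic imprecise manual annotation).

It makes no attempt at photorealistic histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import disk as disk_indices

from .categories import CATEGORIES, DEFAULT_SUBCATEGORY, Category, SubCategory
from .raster import rasterize_polygon
from .slide_io import (
    AnnotationSet,
    ArraySlidePyramid,
    Manifest,
    PolygonAnnotation,
    SlideRecord,
    build_pyramid_levels,
    write_annotations,
    write_manifest,
    write_slide_dir,
)

__all__ = [
    "TextureModel",
    "DEFAULT_TEXTURES",
    "LesionSpec",
    "SyntheticSlideSpec",
    "generate_slide",
    "plan_cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class TextureModel:
    """Colour/texture signature of one category's tissue.

    ``spot_density`` is simulated nuclei per pixel of region area; spots are
    dark disks of radius ``spot_radius``.  The four default models are
    pairwise separated by at least 0.10 in one RGB channel of the base
    colour, which is what guarantees small-classifier separability.
    """

    base_rgb: tuple[float, float, float]
    spot_density: float
    spot_radius: int = 2
    noise_sd: float = 0.02
    spot_rgb: tuple[float, float, float] = (0.24, 0.14, 0.36)


DEFAULT_TEXTURES: dict[Category, TextureModel] = {
    Category.NORMAL: TextureModel((0.88, 0.72, 0.82), 0.0015),
    Category.LOW_GRADE: TextureModel((0.78, 0.56, 0.76), 0.0035),
    Category.HIGH_GRADE: TextureModel((0.62, 0.42, 0.72), 0.0060),
    Category.MALIGNANT: TextureModel((0.46, 0.30, 0.56), 0.0100),
}

# Deterministic per-lab stain shift (RGB offsets), one row per lab 1..8.
LAB_STAIN_SHIFTS = np.array(
    [
        [0.000, 0.000, 0.000],
        [0.020, -0.010, 0.000],
        [-0.015, 0.010, 0.010],
        [0.010, 0.015, -0.015],
        [-0.020, -0.015, 0.015],
        [0.015, 0.000, 0.020],
        [0.000, 0.020, -0.010],
        [-0.010, -0.020, -0.020],
    ]
)

_BACKGROUND_MEAN = 0.965
_BACKGROUND_SD = 0.006
_BACKGROUND_FLOOR = 0.94  # keeps the >= 0.92 invariant after lab shifts


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: a star-shaped polygon painted with its category texture."""

    category: Category
    center: tuple[float, float]  # (x, y) level-0
    radius: float
    n_vertices: int = 12
    subcategory: SubCategory | None = None


@dataclass
class SyntheticSlideSpec:
    width: int = 512
    height: int = 512
    n_levels: int = 6
    tissue_blob_count: int = 3
    tissue_radius_range: tuple[float, float] = (0.18, 0.30)  # fraction of min dim
    lesions: list[LesionSpec] = field(default_factory=list)
    lab_id: int = 1
    seed: int = 0
    textures: dict[Category, TextureModel] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    annotation_jitter: float = 0.0  # +dilate / -erode polygons, level-0 px
    slide_id: str = "synthetic"


def _star_polygon(
    center: tuple[float, float], radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Random star-convex polygon with vertices within ``radius`` of center."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.55, 1.0, n) * radius
    x = center[0] + radii * np.cos(angles)
    y = center[1] + radii * np.sin(angles)
    return np.stack([x, y], axis=1)


def _paint_spots(
    canvas: np.ndarray,
    mask: np.ndarray,
    tex: TextureModel,
    rng: np.random.Generator,
) -> None:
    area = int(mask.sum())
    n_spots = rng.poisson(tex.spot_density * area)
    if n_spots == 0:
        return
    ys, xs = np.nonzero(mask)
    idx = rng.integers(0, len(ys), n_spots)
    h, w = mask.shape
    for y, x in zip(ys[idx], xs[idx]):
        rr, cc = disk_indices((y, x), tex.spot_radius, shape=(h, w))
        keep = mask[rr, cc]
        canvas[rr[keep], cc[keep]] = tex.spot_rgb


def generate_slide(
    spec: SyntheticSlideSpec, out_dir: str | Path | None = None
) -> tuple[ArraySlidePyramid, AnnotationSet]:
    """Render one synthetic slide and its annotation set.

    The same spec (including seed) always produces byte-identical output.
    Raises if a lesion polygon does not lie inside the tissue mask.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # Tissue: union of random disks, kept inside a margin.  Disk parameters
    # are drawn first so cohort planning can replay this cheap prefix of the
    # random stream when placing lesions.
    tissue = np.zeros((h, w), dtype=bool)
    disk_params = _draw_tissue_disks(spec, rng)
    for cx, cy, r in disk_params:
        rr, cc = disk_indices((cy, cx), r, shape=(h, w))
        tissue[rr, cc] = True

    canvas = np.clip(
        rng.normal(_BACKGROUND_MEAN, _BACKGROUND_SD, (h, w, 3)),
        _BACKGROUND_FLOOR,
        1.0,
    )
    tex_normal = spec.textures[Category.NORMAL]
    noise = rng.normal(0.0, tex_normal.noise_sd, (h, w, 3))
    canvas[tissue] = np.clip(
        np.asarray(tex_normal.base_rgb) + noise[tissue], 0.0, 1.0
    )
    _paint_spots(canvas, tissue, tex_normal, rng)

    # Paint in ascending severity so a more severe lesion is never covered
    # by a milder one; annotations list follows the same order.
    polygons: list[PolygonAnnotation] = []
    for lesion in sorted(spec.lesions, key=lambda l: l.category.severity_rank):
        verts = _star_polygon(lesion.center, lesion.radius, lesion.n_vertices, rng)
        mask = rasterize_polygon(verts, (h, w))
        if mask.sum() == 0 or (mask & ~tissue).any():
            raise ValueError(
                f"lesion at {lesion.center} (r={lesion.radius:.1f}) "
                "falls outside tissue"
            )
        tex = spec.textures[lesion.category]
        canvas[mask] = np.clip(np.asarray(tex.base_rgb) + noise[mask], 0.0, 1.0)
        _paint_spots(canvas, mask, tex, rng)

        ann_verts = verts
        if spec.annotation_jitter != 0.0:
            jittered = ShapelyPolygon(verts).buffer(spec.annotation_jitter)
            ann_verts = np.asarray(jittered.exterior.coords[:-1])
        polygons.append(
            PolygonAnnotation(
                vertices=ann_verts,
                category=lesion.category,
                subcategory=lesion.subcategory
                or DEFAULT_SUBCATEGORY[lesion.category],
            )
        )

    if polygons:
        slide_label = max((p.category for p in polygons), key=lambda c: c.severity_rank)
        slide_sublabel = next(
            p.subcategory for p in polygons if p.category is slide_label
        )
    else:
        slide_label = Category.NORMAL
        slide_sublabel = SubCategory.NORMAL_INFLAMMATION

    canvas = canvas + LAB_STAIN_SHIFTS[spec.lab_id - 1]
    level0 = np.clip(np.round(canvas * 255.0), 0, 255).astype(np.uint8)
    levels = build_pyramid_levels(level0, spec.n_levels)
    pyramid = ArraySlidePyramid(levels, slide_id=spec.slide_id)
    annotations = AnnotationSet(
        polygons=polygons, slide_label=slide_label, slide_sublabel=slide_sublabel
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_slide_dir(levels, out_dir / spec.slide_id, slide_id=spec.slide_id)
        write_annotations(annotations, out_dir / f"{spec.slide_id}.json")
    return pyramid, annotations


def _draw_tissue_disks(
    spec: SyntheticSlideSpec, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Draw tissue disk parameters ``(cx, cy, r)`` from the spec's stream."""
    h, w = spec.height, spec.width
    rmin, rmax = spec.tissue_radius_range
    min_dim = min(h, w)
    params = []
    for _ in range(spec.tissue_blob_count):
        r = rng.uniform(rmin, rmax) * min_dim
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        params.append((cx, cy, r))
    return params


def _lesion_specs_for(
    category: Category,
    disk_params: list[tuple[float, float, float]],
    rng: np.random.Generator,
) -> list[LesionSpec]:
    """Place lesions of ``category`` (plus sometimes one milder lesion)."""
    if category is Category.NORMAL:
        return []
    lesions = []
    n_primary = int(rng.integers(1, 3))
    order = rng.permutation(len(disk_params))
    slots = [disk_params[i] for i in order]
    for i in range(n_primary):
        cx, cy, r = slots[i % len(slots)]
        radius = max(3.0, rng.uniform(0.35, 0.6) * (r - 4))
        # offset keeps the star polygon strictly inside its tissue disk
        off = rng.uniform(-0.25, 0.25, 2) * max(0.0, r - 4 - radius)
        lesions.append(
            LesionSpec(category=category, center=(cx + off[0], cy + off[1]), radius=radius)
        )
    if category.severity_rank >= 2 and rng.random() < 0.5 and len(slots) > n_primary:
        milder = CATEGORIES[int(rng.integers(1, category.severity_rank))]
        cx, cy, r = slots[n_primary]
        radius = max(3.0, rng.uniform(0.3, 0.5) * (r - 4))
        lesions.append(LesionSpec(category=milder, center=(cx, cy), radius=radius))
    return lesions


def _plan_slide_spec(
    category: Category,
    size_range: tuple[int, int],
    lab_id: int,
    seed: int,
    slide_id: str,
    jitter: float,
) -> SyntheticSlideSpec:
    rng = np.random.default_rng(seed)
    w = int(rng.integers(size_range[0], size_range[1] + 1))
    h = int(rng.integers(size_range[0], size_range[1] + 1))
    spec = SyntheticSlideSpec(
        width=w,
        height=h,
        tissue_blob_count=int(rng.integers(2, 4)),
        lab_id=lab_id,
        seed=int(rng.integers(0, 2**31 - 1)),
        slide_id=slide_id,
        annotation_jitter=jitter,
    )
    # Reproduce the tissue-disk layout generate_slide will draw (disks are
    # the first draws of its stream), so lesions can be planned inside tissue.
    disk_params = _draw_tissue_disks(spec, np.random.default_rng(spec.seed))
    lrng = np.random.default_rng(seed + 1)
    spec.lesions = _lesion_specs_for(category, disk_params, lrng)
    return spec


def plan_cohort(
    n_slides: int,
    category_mix: dict[Category, float],
    n_labs: int,
    seed: int,
) -> list[tuple[str, int, Category, int]]:
    """Draw the cohort plan: ``(slide_id, lab_id, category, slide_seed)`` rows.

    Categories are drawn independently from ``category_mix``; lab ids are
    assigned round-robin.  This is exactly the random stream
    :func:`generate_cohort` consumes, so the plan can be inspected (e.g.
    for category-count statistics) without rendering any slide.
    """
    cats = list(category_mix)
    probs = np.asarray([category_mix[c] for c in cats], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("category_mix must sum to 1")
    if not 3 <= n_labs <= 8:
        raise ValueError("n_labs must be in 3..8 (two labs are held out at split)")
    rng = np.random.default_rng(seed)
    plan = []
    for i in range(n_slides):
        category = cats[int(rng.choice(len(cats), p=probs))]
        slide_seed = int(rng.integers(0, 2**31 - 1))
        plan.append((f"slide_{i:04d}", (i % n_labs) + 1, category, slide_seed))
    return plan


def generate_cohort(
    n_slides: int,
    category_mix: dict[Category, float],
    n_labs: int,
    seed: int,
    out_dir: str | Path,
    size_range: tuple[int, int] = (512, 1024),
    annotation_jitter: float = 0.0,
) -> Manifest:
    """Generate a full synthetic cohort: slides, annotations and manifest.

    Per-slide categories are drawn from ``category_mix``; lab ids are
    assigned round-robin over ``1..n_labs``.  ``n_labs`` must be at least 3
    so a two-lab hold-out split remains possible downstream.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for slide_id, lab_id, category, slide_seed in plan_cohort(
        n_slides, category_mix, n_labs, seed
    ):
        spec = _plan_slide_spec(
            category, size_range, lab_id, slide_seed, slide_id, annotation_jitter
        )
        _, ann = generate_slide(spec, out_dir=out_dir)
        records.append(
            SlideRecord(
                slide_id=slide_id,
                lab_id=lab_id,
                category=ann.slide_label,
                subcategory=ann.slide_sublabel,
                image_path=slide_id,
                annotation_path=f"{slide_id}.json",
            )
        )
    manifest = Manifest(records=records, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
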