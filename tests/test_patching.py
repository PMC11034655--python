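"""Grid finding, tissue detection, max-severity labelling and sampling."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from wsitriage.categories import CATEGORIES, Category, SubCategory
from wsitriage.patching import (
    GridSpec,
    PatchCoord,
    PatchRecord,
    TissueParams,
    build_patch_table,
    detect_tissue,
    export_patches,
    find_grid_patches,
    label_patches,
    sample_patches,
)
from wsitriage.slide_io import AnnotationSet, PolygonAnnotation

from conftest import make_lesion_slide


def _ann(polys):
    annotations = [
        PolygonAnnotation(
            vertices=np.asarray(v, dtype=float),
            category=c,
            subcategory={
                Category.MALIGNANT: SubCategory.SQUAMOUS_CARCINOMA,
                Category.HIGH_GRADE: SubCategory.CIN2,
                Category.LOW_GRADE: SubCategory.HPV,
            }[c],
        )
        for v, c in polys
    ]
    label = max((a.category for a in annotations), key=lambda c: c.severity_rank)
    return AnnotationSet(
        polygons=annotations,
        slide_label=label,
        slide_sublabel=annotations[0].subcategory,
    )


class TestGrid:
    def test_conventional_grid_cell_is_8_thumbnail_pixels(self):
        assert GridSpec(256, 5).cell == 8
        assert GridSpec(64, 3).cell == 8

    def test_16x16_thumbnail_gives_2x2_grid_with_level0_origins(self):
        coords = find_grid_patches((16, 16), GridSpec(256, 5))
        assert len(coords) == 4
        assert {(c.x0, c.y0) for c in coords} == {(0, 0), (0, 256), (256, 0), (256, 256)}

    def test_thumbnail_smaller_than_cell_gives_empty_grid(self):
        assert find_grid_patches((7, 7), GridSpec(256, 5)) == []

    def test_patch_size_not_divisible_by_downsample_is_error(self):
        with pytest.raises(ValueError, match="divisible"):
            GridSpec(100, 5)

    def test_level0_bounds_drop_cells_over_partial_thumbnail_pixels(self):
        # 828 rows at level 3 -> ceil = 104 thumbnail px, but only 12 full
        # 64-px patches fit vertically (13*64 = 832 > 828)
        grid = GridSpec(64, 3)
        coords = find_grid_patches((104, 69), grid, level0_dims=(546, 828))
        assert max(c.y0 for c in coords) + 64 <= 828
        assert max(c.x0 for c in coords) + 64 <= 546

    def test_coordinate_roundtrip(self):
        grid = GridSpec(128, 4)
        for c in find_grid_patches((64, 48), grid):
            assert (c.x0 // 2**grid.mag_level) // grid.cell == c.col
            assert (c.y0 // 2**grid.mag_level) // grid.cell == c.row


class TestTissueDetection:
    def _thumb(self, h=16, w=16):
        return np.full((h, w, 3), 0.98)

    def test_all_white_cell_is_background(self):
        grid = GridSpec(256, 5)
        coords = find_grid_patches((16, 16), grid)
        flags = detect_tissue(self._thumb(), coords, grid)
        assert flags == [False] * 4

    def test_single_pink_pixel_makes_the_patch_tissue(self):
        grid = GridSpec(256, 5)
        thumb = self._thumb()
        thumb[3, 3] = (0.85, 0.55, 0.75)  # one stained pixel
        coords = find_grid_patches((16, 16), grid)
        flags = detect_tissue(thumb, coords, grid)
        assert flags == [True, False, False, False]

    def test_fully_stained_cell_is_tissue(self):
        grid = GridSpec(256, 5)
        thumb = self._thumb()
        thumb[8:, 8:] = (0.7, 0.4, 0.6)
        flags = detect_tissue(thumb, find_grid_patches((16, 16), grid), grid)
        assert flags == [False, False, False, True]

    def test_uint8_and_float_thumbnails_agree(self):
        grid = GridSpec(256, 5)
        thumb = self._thumb()
        thumb[2, 2] = (0.5, 0.3, 0.45)
        coords = find_grid_patches((16, 16), grid)
        f1 = detect_tissue(thumb, coords, grid)
        f2 = detect_tissue((thumb * 255).astype(np.uint8), coords, grid)
        assert f1 == f2

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            TissueParams(luminance_max=1.5)


class TestLabelling:
    def _setup(self, polys, thumb=(16, 16), grid=GridSpec(256, 5)):
        coords = find_grid_patches(thumb, grid)
        flags = [True] * len(coords)
        return label_patches(coords, flags, _ann(polys), grid, thumb)

    def test_single_malignant_pixel_outranks_high_grade(self):
        # cell 0 is almost fully high grade with a one-pixel malignant spec
        big_hg = [[0, 0], [255, 0], [255, 255], [0, 255]]
        tiny_mal = [[30, 30], [66, 30], [66, 66], [30, 66]]  # ~1 thumbnail px
        records = self._setup(
            [(big_hg, Category.HIGH_GRADE), (tiny_mal, Category.MALIGNANT)]
        )
        assert records[0].label is Category.MALIGNANT

    def test_low_plus_high_overlap_is_high(self):
        lg = [[0, 0], [200, 0], [200, 200], [0, 200]]
        hg = [[100, 100], [250, 100], [250, 250], [100, 250]]
        records = self._setup([(lg, Category.LOW_GRADE), (hg, Category.HIGH_GRADE)])
        assert records[0].label is Category.HIGH_GRADE

    def test_tissue_patch_without_polygon_is_normal(self):
        poly = [[0, 0], [100, 0], [100, 100], [0, 100]]
        records = self._setup([(poly, Category.MALIGNANT)])
        assert records[3].label is Category.NORMAL  # bottom-right cell untouched

    def test_non_tissue_patches_have_no_label(self):
        grid = GridSpec(256, 5)
        coords = find_grid_patches((16, 16), grid)
        flags = [False] * len(coords)
        ann = _ann([([[0, 0], [100, 0], [50, 80]], Category.MALIGNANT)])
        records = label_patches(coords, flags, ann, grid, (16, 16))
        assert all(r.label is None for r in records)

    def test_label_iff_tissue_invariant(self):
        with pytest.raises(ValueError):
            PatchRecord(PatchCoord(0, 0, 0, 0), True, None)

    def test_dilating_malignant_polygon_never_lowers_severity(self):
        rng = np.random.default_rng(4)
        base = np.array([[100, 100], [180, 120], [160, 200], [110, 190]], float)
        grid = GridSpec(64, 3)
        thumb = (40, 40)
        coords = find_grid_patches(thumb, grid)
        flags = [True] * len(coords)
        before = label_patches(coords, flags, _ann([(base, Category.MALIGNANT)]), grid, thumb)
        dilated = Polygon(base).buffer(25.0)
        verts = np.asarray(dilated.exterior.coords[:-1])
        after = label_patches(coords, flags, _ann([(verts, Category.MALIGNANT)]), grid, thumb)
        for b, a in zip(before, after):
            assert a.label.severity_rank >= b.label.severity_rank

    def test_agrees_with_brute_force_level0_rasterization(self):
        """Thumbnail-exact mode vs per-pixel point-in-polygon oracle."""
        rng = np.random.default_rng(11)
        size = 256
        grid = GridSpec(64, 0)  # exact: grid defined at level 0
        polys = []
        for cat in (Category.LOW_GRADE, Category.HIGH_GRADE, Category.MALIGNANT):
            n = rng.integers(4, 9)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(20, 70, n)
            cx, cy = rng.uniform(60, 190, 2)
            polys.append(
                (np.stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)], 1), cat)
            )
        ann = _ann(polys)
        coords = find_grid_patches((size, size), grid)
        flags = [True] * len(coords)
        got = label_patches(
            coords, flags, ann, grid, (size, size),
            exact_level0=True, slide_dims=(size, size),
        )
        # oracle: shapely point-in-polygon per level-0 pixel, max severity
        sev = np.zeros((size, size), np.int8)
        xs, ys = np.meshgrid(np.arange(size), np.arange(size))
        pts = np.stack([xs.ravel(), ys.ravel()], 1)
        for verts, cat in polys:
            prepped = prep(Polygon(verts))
            inside = np.array([prepped.contains(Point(x, y)) for x, y in pts])
            sev = np.maximum(sev, np.where(inside.reshape(size, size), cat.severity_rank, 0))
        for rec in got:
            block = sev[rec.coord.y0 : rec.coord.y0 + 64, rec.coord.x0 : rec.coord.x0 + 64]
            assert rec.label is CATEGORIES[int(block.max())]


class TestSampling:
    def _table(self, counts):
        rows = []
        i = 0
        for cat, n in counts.items():
            for _ in range(n):
                rows.append(
                    {
                        "slide_id": "s",
                        "row": i,
                        "col": 0,
                        "x0": 0,
                        "y0": 64 * i,
                        "is_tissue": True,
                        "label": cat,
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def test_balanced_takes_min_category_count(self):
        table = self._table({"normal": 100, "low_grade": 10, "high_grade": 20, "malignant": 50})
        out = sample_patches(table, "balanced", seed=0)
        assert out["label"].value_counts().to_dict() == {
            "normal": 10, "low_grade": 10, "high_grade": 10, "malignant": 10,
        }

    def test_imbalanced_keeps_malignant_and_matches_normal(self):
        table = self._table({"normal": 100, "low_grade": 10, "high_grade": 20, "malignant": 50})
        out = sample_patches(table, "imbalanced", seed=0)
        assert out["label"].value_counts().to_dict() == {
            "normal": 50, "malignant": 50, "high_grade": 20, "low_grade": 10,
        }

    def test_max_per_category_caps_balanced_sampling(self):
        table = self._table({"normal": 9, "low_grade": 9, "high_grade": 9, "malignant": 9})
        out = sample_patches(table, "balanced", max_per_category=5, seed=0)
        assert (out["label"].value_counts() == 5).all()

    def test_sampling_is_deterministic(self):
        table = self._table({"normal": 40, "low_grade": 9, "high_grade": 9, "malignant": 12})
        o1 = sample_patches(table, "imbalanced", seed=5)
        o2 = sample_patches(table, "imbalanced", seed=5)
        pd.testing.assert_frame_equal(o1, o2)

    def test_balanced_with_empty_category_is_error(self):
        table = self._table({"normal": 5, "low_grade": 5, "high_grade": 5})
        with pytest.raises(ValueError, match="empty"):
            sample_patches(table, "balanced", seed=0)


class TestExport:
    def test_export_writes_category_folders_and_is_idempotent(self, tmp_path):
        pyr, ann, _ = make_lesion_slide(Category.MALIGNANT, seed=2, size=320)
        grid = GridSpec(64, 3)
        table = build_patch_table(pyr, ann, grid, slide_id="s0")
        sampled = table[(table["label"] == "malignant")].head(3)
        paths = export_patches(pyr, sampled, tmp_path, 64)
        assert len(paths) == 3
        assert all(p.parent.name == "malignant" for p in paths)
        first = paths[0].read_bytes()
        export_patches(pyr, sampled, tmp_path, 64)
        assert paths[0].read_bytes() == first

    def test_out_of_bounds_record_is_error(self, tmp_path):
        pyr, ann, _ = make_lesion_slide(Category.NORMAL, seed=1, size=192)
        bad = pd.DataFrame(
            [{"slide_id": "s", "row": 0, "col": 0, "x0": 100000, "y0": 0,
              "is_tissue": True, "label": "normal"}]
        )
        with pytest.raises(ValueError, match="outside"):
            export_patches(pyr, bad, tmp_path, 64)
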