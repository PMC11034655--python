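"""Slide-level feature extraction from category heatmaps."""

import numpy as np
import pytest

from wsitriage.categories import CATEGORIES, Category
from wsitriage.heatmaps import CategoryHeatmaps
from wsitriage.slide_features import (
    BOOSTED_FEATURE_MASKS,
    assemble_boosted_vector,
    assemble_forest_vector,
    boosted_feature_names,
    extract_regions,
    forest_feature_names,
    global_features_boosted,
    global_features_forest,
    region_features_forest,
)

from test_heatmaps import normal_only_heatmaps, probs_frame
from wsitriage.heatmaps import build_heatmaps


def heatmaps_from_grid(mal_grid, tissue=None):
    """Heatmaps with the given malignant grid; residual mass on normal."""
    mal_grid = np.asarray(mal_grid, float)
    mask = np.ones_like(mal_grid, bool) if tissue is None else tissue
    grids = {c: np.zeros_like(mal_grid) for c in CATEGORIES}
    grids[Category.MALIGNANT] = np.where(mask, mal_grid, 0.0)
    grids[Category.NORMAL] = np.where(mask, 1.0 - mal_grid, 0.0)
    return CategoryHeatmaps(grids=grids, tissue_mask=mask)


def random_heatmaps(seed=0, shape=(10, 10)):
    rng = np.random.default_rng(seed)
    raw = rng.dirichlet(np.ones(4) * 0.4, size=shape)
    mask = rng.uniform(size=shape) < 0.7
    grids = {}
    for i, c in enumerate(CATEGORIES):
        g = raw[..., i].copy()
        g[~mask] = 0.0
        grids[c] = g
    if not mask.any():
        mask[0, 0] = True
    return CategoryHeatmaps(grids=grids, tissue_mask=mask)


class TestGlobalFeatures:
    def test_forest_global_block_has_30_values(self):
        assert len(global_features_forest(random_heatmaps())) == 30

    def test_boosted_global_block_has_6_values(self):
        assert len(global_features_boosted(random_heatmaps())) == 6

    def test_normal_only_heatmaps_give_all_zero_globals(self):
        h = normal_only_heatmaps()
        assert not global_features_forest(h).any()
        assert not global_features_boosted(h).any()

    def test_single_cell_malignant_09(self):
        h = heatmaps_from_grid([[0.9]])
        vec = global_features_forest(h)
        # malignant block first: (area_ratio, prob_area) at each threshold <= 0.9
        for k in range(5):
            assert vec[2 * k] == 1.0
            assert vec[2 * k + 1] == pytest.approx(0.9)
        # high-grade and low-grade blocks all zero
        assert not vec[10:].any()

    def test_all_malignant_certain_gives_unit_area_ratios(self):
        h = heatmaps_from_grid(np.ones((3, 3)))
        vec = global_features_boosted(h)
        np.testing.assert_allclose(vec[:3], 1.0)

    def test_no_tissue_is_error(self):
        grids = {c: np.zeros((2, 2)) for c in CATEGORIES}
        h = CategoryHeatmaps(grids=grids, tissue_mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="tissue"):
            global_features_forest(h)

    def test_area_ratio_and_prob_area_nonincreasing_in_threshold(self):
        for seed in range(3):
            vec = global_features_forest(random_heatmaps(seed))
            for block in range(3):
                ar = vec[block * 10 : block * 10 + 10 : 2]
                pa = vec[block * 10 + 1 : block * 10 + 10 : 2]
                assert (np.diff(ar) <= 1e-12).all()
                assert (np.diff(pa) <= 1e-12).all()


class TestRegions:
    def test_diagonal_touch_is_one_region_under_8_connectivity(self):
        binary = np.zeros((4, 4), bool)
        binary[0, 0] = binary[1, 1] = True
        regions = extract_regions(binary, np.ones((4, 4)))
        assert len(regions) == 1
        assert regions[0].pixel_count == 2

    def test_k_largest_by_pixel_count(self):
        binary = np.zeros((8, 8), bool)
        binary[0, :5] = True          # 5 cells
        binary[3, :3] = True          # 3 cells
        binary[6, 0] = True           # 1 cell
        regions = extract_regions(binary, np.ones((8, 8)), k=2)
        assert [r.pixel_count for r in regions] == [5, 3]

    def test_size_ties_break_by_row_major_position(self):
        binary = np.zeros((6, 6), bool)
        binary[4, :2] = True  # lower region, same size
        binary[0, 3:5] = True  # upper region appears first row-major
        regions = extract_regions(binary, np.ones((6, 6)))
        assert regions[0].seed_index < regions[1].seed_index

    def test_matches_brute_force_flood_fill_on_random_masks(self):
        """8-connected labelling vs an independent BFS flood fill."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            mask = rng.uniform(size=(20, 20)) < 0.35
            regions = extract_regions(mask, np.ones_like(mask, float))
            # oracle: BFS flood fill with 8-neighbourhood
            seen = np.zeros_like(mask, bool)
            sizes = []
            for r in range(20):
                for c in range(20):
                    if mask[r, c] and not seen[r, c]:
                        stack, size = [(r, c)], 0
                        seen[r, c] = True
                        while stack:
                            y, x = stack.pop()
                            size += 1
                            for dy in (-1, 0, 1):
                                for dx in (-1, 0, 1):
                                    yy, xx = y + dy, x + dx
                                    if (
                                        0 <= yy < 20 and 0 <= xx < 20
                                        and mask[yy, xx] and not seen[yy, xx]
                                    ):
                                        seen[yy, xx] = True
                                        stack.append((yy, xx))
                        sizes.append(size)
            assert sorted(r.pixel_count for r in regions) == sorted(sizes)

    def test_empty_mask_gives_no_regions(self):
        assert extract_regions(np.zeros((5, 5), bool), np.zeros((5, 5))) == []


class TestRegionFeatures:
    def test_single_cell_region(self):
        binary = np.zeros((3, 3), bool)
        binary[1, 1] = True
        intensity = np.zeros((3, 3))
        intensity[1, 1] = 0.7
        region = extract_regions(binary, intensity)[0]
        vec = region_features_forest(region)
        names = (
            "area eccentricity extent bbox_area major_axis max mean min aspect solidity"
        ).split()
        got = dict(zip(names, vec))
        assert got["area"] == 1 and got["bbox_area"] == 1 and got["extent"] == 1
        assert got["max"] == got["mean"] == got["min"] == pytest.approx(0.7)
        assert got["solidity"] == 1 and got["aspect"] == 1

    def test_2x3_solid_rectangle(self):
        binary = np.zeros((6, 6), bool)
        binary[2:4, 1:4] = True  # 2 rows x 3 cols
        region = extract_regions(binary, np.full((6, 6), 0.5))[0]
        vec = region_features_forest(region)
        assert vec[0] == 6          # area
        assert vec[2] == 1.0        # extent
        assert vec[3] == 6          # bbox area
        assert vec[8] == pytest.approx(3 / 2)  # bbox aspect ratio w/h
        assert vec[9] == 1.0        # solidity

    def test_output_length_is_always_10(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            mask = np.random.default_rng(seed).uniform(size=(8, 8)) < 0.4
            if not mask.any():
                continue
            region = extract_regions(mask, rng.uniform(size=(8, 8)))[0]
            assert len(region_features_forest(region)) == 10

    def test_second_moment_features_match_direct_formulas(self):
        """Eccentricity and axis lengths from the pixel-coordinate covariance."""
        rng = np.random.default_rng(7)
        checked = 0
        for seed in range(30):
            mask = np.random.default_rng(seed).uniform(size=(7, 7)) < 0.35
            regions = extract_regions(mask, rng.uniform(size=(7, 7)))
            for region in regions:
                if not 2 <= region.pixel_count <= 30:
                    continue
                # direct second-moment computation on this region's cells
                cells = self._region_cells(mask, region.seed_index)
                cov = np.cov(cells.T, bias=True)
                lam = np.sort(np.linalg.eigvalsh(cov))
                major = 4 * np.sqrt(lam[1])
                minor = 4 * np.sqrt(lam[0])
                ecc = np.sqrt(1 - lam[0] / lam[1]) if lam[1] > 0 else 0.0
                assert region.feature("major_axis_length") == pytest.approx(major)
                assert region.feature("minor_axis_length") == pytest.approx(minor)
                assert region.feature("eccentricity") == pytest.approx(ecc)
                # area-derived quantities
                a = region.pixel_count
                assert region.feature("equivalent_diameter") == pytest.approx(
                    np.sqrt(4 * a / np.pi)
                )
                checked += 1
        assert checked >= 10

    @staticmethod
    def _region_cells(mask, seed_index):
        """Cells of the 8-connected component containing seed_index."""
        h, w = mask.shape
        start = divmod(seed_index, w)
        seen = {start}
        stack = [start]
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and (yy, xx) not in seen:
                        seen.add((yy, xx))
                        stack.append((yy, xx))
        return np.array(sorted(seen), dtype=float)


class TestVectors:
    def test_forest_vector_length_90(self):
        assert len(assemble_forest_vector(random_heatmaps())) == 90
        assert len(forest_feature_names()) == 90

    def test_forest_regional_block_is_60(self):
        assert len(assemble_forest_vector(random_heatmaps())) - len(
            global_features_forest(random_heatmaps())
        ) == 60

    def test_normal_only_heatmaps_give_90_zeros(self):
        vec = assemble_forest_vector(normal_only_heatmaps())
        assert len(vec) == 90 and not vec.any()

    def test_boosted_vector_length_182(self):
        # 6 + 7*12 + 5*11 + 3*9 + 2*5, per the regional feature masks
        assert len(assemble_boosted_vector(random_heatmaps())) == 182
        assert len(boosted_feature_names()) == 182

    def test_boosted_high_grade_block_excludes_min_intensity(self):
        assert "min_intensity" not in BOOSTED_FEATURE_MASKS[Category.HIGH_GRADE]
        names = boosted_feature_names()
        assert not any(
            n.startswith("high_grade_r") and n.endswith("min_intensity") for n in names
        )
        assert any(
            n.startswith("malignant_r") and n.endswith("min_intensity") for n in names
        )

    def test_normal_only_boosted_vector_is_all_zero(self):
        vec = assemble_boosted_vector(normal_only_heatmaps(tissue_cells=((0, 0),)))
        # the normal heatmap itself has regions (prob 1 >= 0.5): only the
        # normal blocks may be non-zero
        names = boosted_feature_names()
        nonzero = {n for n, v in zip(names, vec) if v != 0}
        assert all(n.startswith("normal_") for n in nonzero)

    def test_features_invariant_to_patch_enumeration_order(self):
        rows = [
            (0, 0, 0.1, 0.2, 0.3, 0.4),
            (1, 1, 0.7, 0.1, 0.1, 0.1),
            (2, 2, 0.0, 0.0, 0.2, 0.8),
        ]
        h1 = build_heatmaps(probs_frame(rows), (3, 3))
        h2 = build_heatmaps(probs_frame(rows[::-1]), (3, 3))
        np.testing.assert_array_equal(
            assemble_forest_vector(h1), assemble_forest_vector(h2)
        )
        np.testing.assert_array_equal(
            assemble_boosted_vector(h1), assemble_boosted_vector(h2)
        )
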