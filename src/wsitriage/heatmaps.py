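"""Per-category probability heatmaps on the patch grid.

One heatmap cell per patch; the four category grids of a tissue cell hold
that patch's softmax probabilities (summing to 1), non-tissue cells are
zero everywhere.  No smoothing or interpolation is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .categories import CATEGORIES, Category

__all__ = [
    "CategoryHeatmaps",
    "build_heatmaps",
    "threshold_heatmap",
    "prediction_map",
    "render_prediction",
    "save_heatmaps",
    "UNCLASSIFIED",
    "BACKGROUND",
]

UNCLASSIFIED = -1
BACKGROUND = -2

#: Rendering palette: normal grey, low grade green, high grade blue,
#: malignant red; unclassified tissue is black, background white.
PALETTE = {
    Category.NORMAL.value: (128, 128, 128),
    Category.LOW_GRADE.value: (0, 160, 0),
    Category.HIGH_GRADE.value: (0, 64, 224),
    Category.MALIGNANT.value: (224, 0, 0),
    "unclassified": (0, 0, 0),
    "background": (255, 255, 255),
}


@dataclass
class CategoryHeatmaps:
    """Four (n_rows, n_cols) probability grids plus the tissue mask."""

    grids: dict[Category, np.ndarray]
    tissue_mask: np.ndarray

    def __post_init__(self):
        shape = self.tissue_mask.shape
        for cat in CATEGORIES:
            if cat not in self.grids or self.grids[cat].shape != shape:
                raise ValueError("need one grid per category, same shape as mask")
        stack = self.stacked()
        sums = stack.sum(axis=0)
        if self.tissue_mask.any() and not np.allclose(
            sums[self.tissue_mask], 1.0, atol=1e-6
        ):
            raise ValueError("tissue-cell probabilities must sum to 1")
        if (stack[:, ~self.tissue_mask] != 0).any():
            raise ValueError("non-tissue cells must be zero in all grids")

    @property
    def tissue_area(self) -> int:
        return int(self.tissue_mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_mask.shape

    def stacked(self) -> np.ndarray:
        """(4, n_rows, n_cols) array in severity order."""
        return np.stack([self.grids[c] for c in CATEGORIES])


def build_heatmaps(
    patch_probs: pd.DataFrame, grid_dims: tuple[int, int]
) -> CategoryHeatmaps:
    """Assemble heatmaps from per-patch probabilities.

    ``patch_probs`` is the inference output (tissue rows with ``row``,
    ``col`` and one ``p_<category>`` column per category);
    ``grid_dims=(n_rows, n_cols)``.  Duplicate cell assignments are errors.
    """
    n_rows, n_cols = grid_dims
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    grids = {c: np.zeros((n_rows, n_cols)) for c in CATEGORIES}
    for rec in patch_probs.itertuples():
        r, c = int(rec.row), int(rec.col)
        if mask[r, c]:
            raise ValueError(f"duplicate patch assignment for cell ({r}, {c})")
        mask[r, c] = True
        for cat in CATEGORIES:
            grids[cat][r, c] = getattr(rec, f"p_{cat.value}")
    return CategoryHeatmaps(grids=grids, tissue_mask=mask)


def threshold_heatmap(grid: np.ndarray, t: float) -> np.ndarray:
    """Binary mask of cells with probability >= t (inclusive threshold)."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return np.asarray(grid) >= t


def prediction_map(h: CategoryHeatmaps, t: float = 0.5) -> np.ndarray:
    """Per-cell predicted category index (severity rank).

    Tissue cells take the argmax category if its probability reaches ``t``
    (ties broken toward higher severity), else ``UNCLASSIFIED``; non-tissue
    cells are ``BACKGROUND``.
    """
    stack = h.stacked()
    # reversed argmax picks the highest-severity category on ties
    rev = stack[::-1]
    winner = len(CATEGORIES) - 1 - rev.argmax(axis=0)
    peak = stack.max(axis=0)
    out = np.where(peak >= t, winner, UNCLASSIFIED)
    out[~h.tissue_mask] = BACKGROUND
    return out.astype(int)


def render_prediction(pred: np.ndarray, cell_px: int = 8) -> Image.Image:
    """Render a prediction map with the fixed palette, one cell = cell_px."""
    colors = {
        BACKGROUND: PALETTE["background"],
        UNCLASSIFIED: PALETTE["unclassified"],
        **{c.severity_rank: PALETTE[c.value] for c in CATEGORIES},
    }
    rgb = np.zeros((*pred.shape, 3), dtype=np.uint8)
    for code, col in colors.items():
        rgb[pred == code] = col
    img = Image.fromarray(rgb)
    return img.resize(
        (pred.shape[1] * cell_px, pred.shape[0] * cell_px), Image.NEAREST
    )


def save_heatmaps(
    h: CategoryHeatmaps,
    out_dir: str | Path,
    slide_id: str,
    patch_size: int,
    mag_level: int,
    t: float = 0.5,
) -> Path:
    """Write per-category heatmap PNGs, a prediction PNG and a sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cat in CATEGORIES:
        arr = np.clip(np.round(h.grids[cat] * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / f"{slide_id}_{cat.value}.png")
    render_prediction(prediction_map(h, t)).save(
        out_dir / f"{slide_id}_prediction.png"
    )
    sidecar = {
        "slide_id": slide_id,
        "n_rows": int(h.shape[0]),
        "n_cols": int(h.shape[1]),
        "patch_size": patch_size,
        "mag_level": mag_level,
        "tissue_area": h.tissue_area,
        "threshold": t,
    }
    path = out_dir / f"{slide_id}_heatmaps.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path
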