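"""Polygon rasterization shared by annotation labelling and the generator."""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon2mask


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    ``vertices`` are (x, y) coordinates; ``shape`` is (height, width).
    """
    return polygon2mask(shape, np.asarray(vertices, dtype=float)[:, ::-1])
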