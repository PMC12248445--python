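"""Ion-image and segment-map rendering."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .msi_io import FeatureMatrix

__all__ = ["render_ion_image", "render_segment_map", "save_image"]


def _feature_index(matrix: FeatureMatrix, mz: float, tolerance_ppm: float = 20.0) -> int:
    ppm = np.abs(matrix.mz_axis - mz) / mz * 1e6
    j = int(np.argmin(ppm))
    if ppm[j] > tolerance_ppm:
        raise KeyError(f"no feature within {tolerance_ppm} ppm of m/z {mz}")
    return j


def render_ion_image(matrix: FeatureMatrix, mz: float, colormap: str = "viridis",
                     scale: str = "linear", clip_quantile: float = 0.99) -> np.ndarray:
    """Map one feature's per-pixel intensity to an RGBA image.

    ``scale='linear'`` normalizes by the maximum; ``'quantile'`` clips at the
    ``clip_quantile`` percentile first (hotspot suppression).  Background
    pixels (no spectrum) are fully transparent.
    """
    import matplotlib.pyplot as plt

    j = _feature_index(matrix, mz)
    vals = matrix.dense_values()[:, j]
    if scale == "quantile":
        top = np.quantile(vals, clip_quantile)
        vals = np.minimum(vals, top) if top > 0 else vals
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    vmax = vals.max()
    norm = vals / vmax if vmax > 0 else vals
    cmap = plt.get_cmap(colormap)
    img = np.zeros(matrix.grid_shape + (4,), dtype=np.uint8)
    rgba = (np.asarray(cmap(norm)) * 255).astype(np.uint8)
    for (r, c), color in zip(matrix.pixel_index, rgba):
        img[r, c] = color
    return img


def render_segment_map(label_grid: np.ndarray, colormap: str = "tab10") -> np.ndarray:
    """RGBA image of a segment/tissue label grid; labels < 0 are transparent."""
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap(colormap)
    img = np.zeros(label_grid.shape + (4,), dtype=np.uint8)
    labs = [int(v) for v in np.unique(label_grid) if v >= 0]
    for i, lab in enumerate(labs):
        color = (np.asarray(cmap(i % cmap.N)) * 255).astype(np.uint8)
        img[label_grid == lab] = color
    return img


def save_image(img: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), img)
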