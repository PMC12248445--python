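"""Datacube containers and standard-format I/O.

A datacube is one centroided spectrum per tissue pixel on a rectangular
raster.  In memory, coordinates are 0-based (row, col), row-major; in imzML
files they are 1-based with x = col + 1 and y = row + 1.  Intensities are
stored float32 on disk and promoted to float64 for computation.  Only
processed-mode (centroided, per-pixel m/z axes) imzML is supported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("lipidmsi")

__all__ = [
    "PixelSpectrum",
    "Datacube",
    "FeatureMatrix",
    "read_imzml",
    "write_imzml",
    "read_label_mask",
    "write_label_mask",
]


@dataclass
class PixelSpectrum:
    """Centroided spectrum at one raster position."""

    mz: np.ndarray
    intensity: np.ndarray
    coord: tuple[int, int]  # (row, col), 0-based

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Datacube:
    """Pixel grid of centroided spectra."""

    spectra: list[PixelSpectrum]
    grid_shape: tuple[int, int]
    pixel_size: float = 25.0  # micrometers
    mode_polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        rows, cols = self.grid_shape
        seen = set()
        for s in self.spectra:
            r, c = s.coord
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"coordinate {s.coord} outside grid {self.grid_shape}")
            if s.coord in seen:
                raise ValueError(f"duplicate coordinate {s.coord}")
            seen.add(s.coord)

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)


@dataclass
class FeatureMatrix:
    """Aligned pixels x features intensity table."""

    mz_axis: np.ndarray  # feature m/z, ascending
    values: np.ndarray  # (n_pixels, n_features), >= 0
    pixel_index: list[tuple[int, int]]  # coord per row
    grid_shape: tuple[int, int]
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from scipy import sparse

        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        if not sparse.issparse(self.values):
            self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.pixel_index), self.mz_axis.size):
            raise ValueError("values shape inconsistent with pixel_index / mz_axis")
        if self.mz_axis.size > 1 and not np.all(np.diff(self.mz_axis) > 0):
            raise ValueError("feature m/z axis must be strictly ascending")
        data = self.values.data if sparse.issparse(self.values) else self.values
        if data.size and data.min() < 0:
            raise ValueError("feature intensities must be non-negative")

    def dense_values(self) -> np.ndarray:
        """Values as a dense float64 array (pre-filter matrices may be sparse)."""
        from scipy import sparse

        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return self.values

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_index)

    @property
    def n_features(self) -> int:
        return int(self.mz_axis.size)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.dense_values(),
            columns=[f"{mz:.6f}" for mz in self.mz_axis],
        )
        df.insert(0, "row", [rc[0] for rc in self.pixel_index])
        df.insert(1, "col", [rc[1] for rc in self.pixel_index])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, grid_shape: tuple[int, int] | None = None,
                 normalized: bool = True) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        rows = df.pop("row").to_numpy(dtype=np.int64)
        cols = df.pop("col").to_numpy(dtype=np.int64)
        if grid_shape is None:
            grid_shape = (int(rows.max()) + 1, int(cols.max()) + 1)
        return cls(
            mz_axis=np.array([float(c) for c in df.columns]),
            values=df.to_numpy(dtype=np.float64),
            pixel_index=list(zip(rows.tolist(), cols.tolist())),
            grid_shape=grid_shape,
            normalized=normalized,
        )


# -- imzML -------------------------------------------------------------------


def write_imzml(cube: Datacube, path: str | Path) -> tuple[Path, Path]:
    """Write a datacube as a processed-mode imzML/ibd pair.

    Returns the (imzML, ibd) paths.  Memory coordinates (row, col) map to file
    coordinates (x, y) = (col + 1, row + 1).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if cube.n_pixels == 0:
        raise ValueError("refusing to write an empty datacube")
    path = Path(path)
    base = path.with_suffix("") if path.suffix.lower() == ".imzml" else path
    with ImzMLWriter(
        str(base),
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        mode="processed",
        polarity=cube.mode_polarity,
    ) as writer:
        for s in cube.spectra:
            r, c = s.coord
            writer.addSpectrum(s.mz, s.intensity.astype(np.float32), (c + 1, r + 1))
    return base.with_suffix(".imzML"), base.with_suffix(".ibd")


def read_imzml(path: str | Path, pixel_size: float = 25.0,
               grid_shape: tuple[int, int] | None = None) -> Datacube:
    """Read a processed-mode imzML file into a Datacube.

    The grid defaults to the file's "max count of pixels" metadata (or the
    maximal occupied coordinate); pass ``grid_shape`` to embed the spectra in
    a larger raster, e.g. when trailing rows/columns are pure background.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    try:
        params = parser.metadata.file_description.param_by_name
    except AttributeError:  # pragma: no cover - very old files
        params = {}
    if params.get("continuous"):
        raise ValueError("continuous-mode imzML is not supported; export processed mode")
    spectra = []
    max_r = max_c = 0
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        r, c = int(y) - 1, int(x) - 1
        order = np.argsort(mz, kind="stable")
        spectra.append(PixelSpectrum(np.asarray(mz)[order], np.asarray(inten, dtype=np.float64)[order], (r, c)))
        max_r, max_c = max(max_r, r), max(max_c, c)
    if grid_shape is None:
        meta = getattr(parser, "imzmldict", {}) or {}
        rows = int(meta.get("max count of pixels y", max_r + 1))
        cols = int(meta.get("max count of pixels x", max_c + 1))
        grid_shape = (max(rows, max_r + 1), max(cols, max_c + 1))
    return Datacube(spectra, grid_shape, pixel_size=pixel_size)


# -- label masks -------------------------------------------------------------


def write_label_mask(grid: np.ndarray, path: str | Path) -> None:
    """Write an integer label image as TSV (``.tsv``) or indexed PNG (``.png``)."""
    grid = np.asarray(grid)
    if not np.issubdtype(grid.dtype, np.integer):
        if not np.all(grid == grid.astype(np.int64)):
            raise ValueError("label mask must contain integer values")
        grid = grid.astype(np.int64)
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if grid.min() < 0 or grid.max() > 255:
            raise ValueError("PNG masks support labels 0-255 only")
        iio.imwrite(path, grid.astype(np.uint8))
    else:
        np.savetxt(path, grid, fmt="%d", delimiter="\t")


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a TSV or indexed-PNG label image as an int array."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # palette expanded to RGB(A): not a label image
            raise ValueError("PNG mask must be single-channel integer labels")
        grid = arr.astype(np.int64)
    else:
        grid = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    if np.all(grid == 0):
        warnings.warn("label mask contains only background", stacklevel=2)
    return grid


def check_mask_matches(grid: np.ndarray, cube_or_shape) -> None:
    """Raise if a mask's dimensions do not match a cube/grid shape."""
    shape = getattr(cube_or_shape, "grid_shape", cube_or_shape)
    if tuple(grid.shape) != tuple(shape):
        raise ValueError(f"mask shape {grid.shape} does not match grid {tuple(shape)}")
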