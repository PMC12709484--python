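"""Grayscale image I/O and region tiling.

Images are handled as 8-bit grayscale fields on the 0-255 intensity scale,
the substrate for every downstream analysis (binarization, box counting,
multifractal measures, optical-lattice potentials).  Region tiling uses
1-based (row, col) tile coordinates so that a tile label like ``(1, 5)``
reads naturally as "first tile row, fifth tile column"; pixel indexing
inside arrays stays 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

# ITU-R BT.601 luminance weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale intensity field with integer values in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D intensity array, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel per axis")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.round(px)):
                raise ValueError("intensities must be integral")
            px = np.round(px).astype(np.int64)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionGrid:
    """Non-overlapping square tiles of an image.

    ``regions`` holds ``(row, col, tile)`` triples with 1-based, row-major
    tile coordinates; tile (1, 1) is the top-left tile.  Remainder pixels
    that do not fill a complete tile are discarded.
    """

    region_size: int
    n_rows: int
    n_cols: int
    regions: tuple

    def get(self, row: int, col: int) -> GrayImage:
        """Return the tile at 1-based coordinates (row, col)."""
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise KeyError(f"tile ({row}, {col}) outside grid "
                           f"{self.n_rows}x{self.n_cols}")
        return self.regions[(row - 1) * self.n_cols + (col - 1)][2]


def read_gray(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF raster as a GrayImage on the 0-255 scale.

    16-bit inputs are linearly rescaled (255 * v / 65535, rounded); RGB(A)
    inputs are converted via BT.601 luminance.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise IOError(f"could not decode {path}: {exc}") from exc
    return gray_from_array(arr)


def gray_from_array(arr: np.ndarray) -> GrayImage:
    """Normalize a decoded raster array (8/16-bit, gray or RGB) to GrayImage."""
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError("zero-sized image")
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(np.float64) @ _LUMA
        else:
            arr = arr[..., 0].astype(np.float64)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster dimensionality {arr.ndim}")
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    elif np.issubdtype(arr.dtype, np.floating):
        if arr.max() > 255:
            arr = arr * (255.0 / arr.max())
    return GrayImage(np.round(np.asarray(arr, dtype=np.float64)).astype(np.int64))


def write_gray(image: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit PNG or TIFF, chosen by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image.pixels)
    else:
        Image.fromarray(image.pixels, mode="L").save(path)


def tile(image: GrayImage, region_size: int) -> RegionGrid:
    """Tile an image into non-overlapping region_size x region_size squares.

    Trailing rows/columns that do not fill a complete tile are dropped
    rather than padded, so no artificial structure enters the analysis.
    """
    if region_size < 2:
        raise ValueError("region_size must be >= 2")
    h, w = image.shape
    if region_size > min(h, w):
        raise ValueError(
            f"region_size {region_size} exceeds image extent {min(h, w)}")
    n_rows, n_cols = h // region_size, w // region_size
    regions = []
    for i in range(n_rows):
        for j in range(n_cols):
            block = image.pixels[i * region_size:(i + 1) * region_size,
                                 j * region_size:(j + 1) * region_size]
            regions.append((i + 1, j + 1, GrayImage(block.copy())))
    return RegionGrid(region_size=region_size, n_rows=n_rows, n_cols=n_cols,
                      regions=tuple(regions))
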