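"""Box-counting fractal dimension of binary masks and per-region Df fields.

The dimension is the least-squares slope of ln N(r) against ln(1/r), where
N(r) counts occupied cells of an axis-aligned grid of side r anchored at the
top-left corner (ragged edge cells are included).  Grid-anchored counting
keeps N(r) exact on self-similar fixtures whose construction scales divide
the image side, which is what makes the estimator testable to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage, tile
from .thresholding import BinaryImage, ThresholdSpec, binarize

#: Default box-size ladder used for 60x60 analysis regions.
DEFAULT_BOX_SIZES = (2, 4, 6, 10, 12)


@dataclass(frozen=True)
class BoxCountResult:
    box_sizes: tuple
    counts: tuple
    df: float
    fit_r2: float


@dataclass(frozen=True)
class DfField:
    """Per-tile fractal dimensions of one image at one threshold.

    ``values`` is an (n_rows, n_cols) array with NaN marking tiles whose
    mask was empty (Df undefined there; such tiles are excluded from the
    aggregates, not coerced to zero).
    """

    region_size: int
    values: np.ndarray
    mean_df: float
    std_df: float
    n_defined: int
    n_excluded: int

    def defined_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def count_boxes(mask: BinaryImage | np.ndarray, r: int) -> int:
    """Number of r x r grid cells containing at least one foreground pixel."""
    if r < 1:
        raise ValueError("box size must be >= 1")
    px = mask.pixels if isinstance(mask, BinaryImage) else np.asarray(mask)
    occ = px.astype(bool)
    rows = np.arange(0, occ.shape[0], r)
    cols = np.arange(0, occ.shape[1], r)
    cells = np.add.reduceat(np.add.reduceat(occ, rows, axis=0), cols, axis=1)
    return int(np.count_nonzero(cells))


def fit_dimension(mask: BinaryImage | np.ndarray,
                  box_sizes=DEFAULT_BOX_SIZES) -> BoxCountResult:
    """Fit Df as the OLS slope of ln N(r) vs ln(1/r) over the given sizes."""
    sizes = tuple(sorted(set(int(r) for r in box_sizes)))
    if len(sizes) < 2:
        raise ValueError("need at least 2 distinct box sizes")
    px = mask.pixels if isinstance(mask, BinaryImage) else np.asarray(mask)
    if not px.any():
        raise ValueError("empty mask: fractal dimension undefined")
    counts = tuple(count_boxes(px, r) for r in sizes)
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return BoxCountResult(box_sizes=sizes, counts=counts, df=float(slope),
                          fit_r2=r2)


def df_field(image: GrayImage, t: ThresholdSpec | int, region_size: int = 60,
             box_sizes=DEFAULT_BOX_SIZES) -> DfField:
    """Binarize once, tile, fit Df per tile, aggregate MeanDf / STDDf.

    STDDf is the sample standard deviation (ddof=1) over tiles with a
    defined Df; it is NaN when fewer than two tiles are defined.
    """
    mask = binarize(image, t)
    grid = tile(GrayImage(mask.pixels * np.uint8(255)), region_size)
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    for row, col, region in grid.regions:
        sub = region.pixels > 0
        if sub.any():
            values[row - 1, col - 1] = fit_dimension(sub, box_sizes).df
    defined = values[np.isfinite(values)]
    n_def = defined.size
    n_exc = values.size - n_def
    if n_def == 0:
        raise ValueError(
            f"all {values.size} regions empty at threshold {t}: Df undefined")
    mean = float(defined.mean())
    std = float(defined.std(ddof=1)) if n_def >= 2 else float("nan")
    return DfField(region_size=region_size, values=values, mean_df=mean,
                   std_df=std, n_defined=n_def, n_excluded=n_exc)
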