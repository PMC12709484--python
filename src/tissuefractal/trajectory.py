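"""Threshold sweeps: fractal-statistic trajectories and group contrasts.

The trajectory of MeanDf (or STDDf) as a function of binarization threshold
separates tissue groups that look similar at any single threshold; the
"optimal threshold" is the grid point maximizing the absolute between-group
difference of the chosen statistic.  Aggregation pools regions across all
images of a group at each threshold (matching pooled distribution plots),
rather than averaging per-image means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .boxcount import DEFAULT_BOX_SIZES, df_field
from .image_io import GrayImage
from .thresholding import ThresholdSpec


@dataclass(frozen=True)
class TrajectoryCurve:
    """Per-threshold pooled statistics of a region-level quantity.

    ``mean_curve`` / ``std_curve`` hold the pooled mean and sample std of the
    per-region values at each threshold; NaN marks thresholds where every
    region of every image was empty (kept in the curve as gaps).
    ``quantity`` names what was pooled ("Df" or "lnDtf").
    """

    thresholds: tuple
    mean_curve: np.ndarray
    std_curve: np.ndarray
    n_regions: np.ndarray
    group_label: str = ""
    quantity: str = "Df"

    def statistic(self, which: str) -> np.ndarray:
        if which == "mean":
            return self.mean_curve
        if which == "std":
            return self.std_curve
        raise ValueError("statistic must be 'mean' or 'std'")


@dataclass(frozen=True)
class GroupContrast:
    """Between-group difference at the grid threshold where it is maximal."""

    optimal_threshold: ThresholdSpec
    value_control: float
    value_disease: float
    abs_diff: float
    percent_change: float
    statistic: str
    quantity: str = "Df"


def pooled_region_values(images, t: ThresholdSpec, region_size: int = 60,
                         box_sizes=DEFAULT_BOX_SIZES) -> np.ndarray:
    """All defined per-region Df values pooled across a list of images."""
    chunks = []
    for img in images:
        try:
            field = df_field(img, t, region_size, box_sizes)
        except ValueError:
            continue  # image entirely empty at this threshold
        chunks.append(field.defined_values())
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def sweep(images, grid, region_size: int = 60, box_sizes=DEFAULT_BOX_SIZES,
          group_label: str = "") -> TrajectoryCurve:
    """MeanDf / STDDf versus threshold, pooled over regions of all images."""
    if len(images) == 0:
        raise ValueError("need at least one image")
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    means, stds, ns = [], [], []
    for t in grid:
        vals = pooled_region_values(images, t, region_size, box_sizes)
        ns.append(vals.size)
        if vals.size == 0:
            means.append(np.nan)
            stds.append(np.nan)
        else:
            means.append(float(vals.mean()))
            stds.append(float(vals.std(ddof=1)) if vals.size > 1 else np.nan)
    return TrajectoryCurve(thresholds=tuple(grid),
                           mean_curve=np.asarray(means),
                           std_curve=np.asarray(stds),
                           n_regions=np.asarray(ns),
                           group_label=group_label)


def optimal_threshold(control: TrajectoryCurve, disease: TrajectoryCurve,
                      statistic: str = "mean",
                      min_regions: int = 10) -> GroupContrast:
    """Grid threshold maximizing |disease - control| of the chosen statistic.

    Ties are broken toward the lowest threshold.  Percent change uses the
    control value as denominator.  Grid entries supported by fewer than
    ``min_regions`` per-region values in either group are not comparable
    statistics (a handful of surviving regions at a nearly-empty or
    nearly-full threshold) and are excluded from the search; set
    ``min_regions=0`` to search every defined entry.
    """
    if tuple(t.gray_level for t in control.thresholds) != \
            tuple(t.gray_level for t in disease.thresholds):
        raise ValueError("curves must share the same threshold grid")
    a = control.statistic(statistic)
    b = disease.statistic(statistic)
    diff = np.abs(b - a)
    defined = (np.isfinite(diff)
               & (control.n_regions >= min_regions)
               & (disease.n_regions >= min_regions))
    if not defined.any():
        raise ValueError("no threshold with both curves defined")
    masked = np.where(defined, diff, -np.inf)
    idx = int(np.argmax(masked))  # first (= lowest-threshold) maximum
    va, vb = float(a[idx]), float(b[idx])
    pct = 100.0 * (vb - va) / va if va != 0 else float("inf") * np.sign(vb - va)
    return GroupContrast(optimal_threshold=control.thresholds[idx],
                         value_control=va, value_disease=vb,
                         abs_diff=float(diff[idx]), percent_change=pct,
                         statistic=statistic, quantity=control.quantity)


@dataclass(frozen=True)
class DfDistribution:
    values: np.ndarray
    hist: np.ndarray
    bin_edges: np.ndarray
    mean: float
    std: float
    skewness: float
    log_scale: bool
    n_excluded: int = 0


def df_distribution(images, t: ThresholdSpec, region_size: int = 60,
                    box_sizes=DEFAULT_BOX_SIZES, log_scale: bool = False,
                    bins: int = 20) -> DfDistribution:
    """Pooled per-region Df (or ln Df) distribution at one threshold."""
    vals = pooled_region_values(images, t, region_size, box_sizes)
    n_excluded = 0
    if log_scale:
        pos = vals > 0
        n_excluded = int(vals.size - pos.sum())
        vals = np.log(vals[pos])
    if vals.size < 2:
        raise ValueError("need at least 2 defined region values")
    hist, edges = np.histogram(vals, bins=bins, density=True)
    if np.ptp(vals) == 0:
        skew = 0.0  # degenerate: all mass in one bin
    else:
        skew = float(sstats.skew(vals))
    return DfDistribution(values=vals, hist=hist, bin_edges=edges,
                          mean=float(vals.mean()),
                          std=float(vals.std(ddof=1)),
                          skewness=skew, log_scale=log_scale,
                          n_excluded=n_excluded)
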