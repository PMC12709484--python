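"""Fractal functional transformation Dtf = Df/(Dfmax - Df) and Gaussianity.

Region-level box-counting dimensions of tissue masks have long-tailed
distributions, which makes their means and standard deviations awkward
summary statistics.  The transformation Dtf = Df / (Dfmax - Df), with
Dfmax = 2 for planar images, stretches the approach to the plane-filling
limit; the natural logarithm ln Dtf is approximately Gaussian, so
Mean(lnDtf) and STD(lnDtf) become well-behaved quantification parameters.

The map is strictly increasing on (0, 2) and exactly invertible:
Df = Dfmax * Dtf / (1 + Dtf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .boxcount import DEFAULT_BOX_SIZES, DfField
from .thresholding import ThresholdSpec
from .trajectory import TrajectoryCurve, pooled_region_values

#: Embedding (maximum) dimension for planar micrographs.
DFMAX = 2.0
#: Pole guard: regions with Df within this distance of DFMAX are excluded.
POLE_DELTA = 1e-9


@dataclass(frozen=True)
class TransformedSample:
    """Dtf and ln Dtf values of the retained regions, plus exclusion counts."""

    dtf: np.ndarray
    ln_dtf: np.ndarray
    dfmax: float
    threshold: ThresholdSpec | None
    n_excluded: int


@dataclass(frozen=True)
class GaussianFit:
    """Chi-square goodness of fit of values against their fitted normal.

    ``score`` is 100 times the chi-square p-value: near 100 for samples
    indistinguishable from Gaussian, near 0 for clearly non-Gaussian ones.
    """

    mean: float
    std: float
    chi_square: float
    dof: int
    p_value: float
    score: float
    n_bins: int


def apply_transform(df_values: np.ndarray, dfmax: float = DFMAX) -> tuple[np.ndarray, int]:
    """Element-wise Dtf on valid inputs; returns (dtf, n_excluded).

    Values with Df <= 0 or Df >= dfmax - POLE_DELTA are excluded (the pole
    at Df = dfmax would otherwise manufacture outliers), never clipped.
    """
    v = np.asarray(df_values, dtype=float)
    valid = np.isfinite(v) & (v > 0) & (v < dfmax - POLE_DELTA)
    kept = v[valid]
    return kept / (dfmax - kept), int(v.size - valid.sum())


def invert_transform(dtf: np.ndarray, dfmax: float = DFMAX) -> np.ndarray:
    """Recover Df = dfmax * Dtf / (1 + Dtf)."""
    d = np.asarray(dtf, dtype=float)
    return dfmax * d / (1.0 + d)


def transform_field(field: DfField, dfmax: float = DFMAX,
                    threshold: ThresholdSpec | None = None) -> TransformedSample:
    """Transform a per-region Df field into Dtf / ln Dtf samples."""
    dtf, n_exc = apply_transform(field.defined_values(), dfmax)
    n_exc += field.n_excluded
    if dtf.size == 0:
        raise ValueError("every region excluded: no transformable Df values")
    return TransformedSample(dtf=dtf, ln_dtf=np.log(dtf), dfmax=dfmax,
                             threshold=threshold, n_excluded=n_exc)


def gaussian_fit(sample, n_bins: int = 10) -> GaussianFit:
    """Pearson chi-square test of a sample against its fitted normal.

    Bins have equal expected probability under the fitted N(mean, std);
    degrees of freedom are n_bins - 3 (two estimated parameters).  Accepts a
    TransformedSample (its ln Dtf values are tested) or any 1D array.
    """
    values = sample.ln_dtf if isinstance(sample, TransformedSample) else \
        np.asarray(sample, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise ValueError("need at least 20 values for a stable chi-square fit")
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    mean = float(values.mean())
    std = float(values.std(ddof=1))
    if std == 0:
        raise ValueError("degenerate (constant) sample")
    inner = sstats.norm.ppf(np.linspace(0, 1, n_bins + 1)[1:-1], mean, std)
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    observed, _ = np.histogram(values, bins=edges)
    expected = values.size / n_bins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = n_bins - 3
    p = float(sstats.chi2.sf(chi2, dof))
    return GaussianFit(mean=mean, std=std, chi_square=chi2, dof=dof,
                       p_value=p, score=100.0 * p, n_bins=n_bins)


def transform_sweep(images, grid, region_size: int = 60,
                    box_sizes=DEFAULT_BOX_SIZES,
                    group_label: str = "") -> TrajectoryCurve:
    """Mean(lnDtf) and STD(lnDtf) versus threshold, pooled over regions.

    Same sweep machinery as the Df trajectory, applied to ln Dtf; the
    resulting curve feeds trajectory.optimal_threshold unchanged.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    means, stds, ns = [], [], []
    for t in grid:
        dfs = pooled_region_values(images, t, region_size, box_sizes)
        dtf, _ = apply_transform(dfs)
        ln_dtf = np.log(dtf) if dtf.size else np.empty(0)
        ns.append(ln_dtf.size)
        if ln_dtf.size == 0:
            means.append(np.nan)
            stds.append(np.nan)
        else:
            means.append(float(ln_dtf.mean()))
            stds.append(float(ln_dtf.std(ddof=1)) if ln_dtf.size > 1 else np.nan)
    return TrajectoryCurve(thresholds=tuple(grid),
                           mean_curve=np.asarray(means),
                           std_curve=np.asarray(stds),
                           n_regions=np.asarray(ns),
                           group_label=group_label,
                           quantity="lnDtf")
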