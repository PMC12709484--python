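"""Direct multifractal spectrum estimation via the mu-measure formalism.

The grayscale intensity field is treated as a mass measure: at box side
epsilon the mass fraction of box i is P(eps, i) = (box intensity sum) /
(total intensity).  For each moment order Q the Q-warped weights

    mu_i(Q, eps) = P_i^Q / sum_j P_j^Q

give the singularity strength and spectrum value directly (no Legendre
transform):

    alpha(Q) = slope over ln eps of  sum_i mu_i ln P_i
    f(Q)     = slope over ln eps of  sum_i mu_i ln mu_i

Both sums are exactly linear in ln eps for exact multiplicative cascades,
which is what the closed-form oracles in the test suite exploit.  Zero-mass
boxes are dropped before exponentiation (P^Q diverges for Q < 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

DEFAULT_Q_GRID = tuple(float(q) for q in np.arange(-10.0, 10.0 + 0.25, 0.5))
DEFAULT_EPS = (2, 4, 6, 10, 12)


@dataclass(frozen=True)
class MeasureField:
    """Normalized per-box mass fractions of a region at one box side."""

    box_side: int
    p: np.ndarray  # 2D grid of box mass fractions, sums to 1

    def positive_masses(self) -> np.ndarray:
        flat = self.p.ravel()
        return flat[flat > 0]


@dataclass(frozen=True)
class MultifractalSpectrum:
    q: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    r2_alpha: np.ndarray
    r2_f: np.ndarray


@dataclass(frozen=True)
class SpectrumParams:
    """Summary parameters of an f(alpha) spectrum.

    Delta-alpha (bandwidth) measures heterogeneity of local scaling;
    Delta-f (height) measures how unevenly the singularities are
    distributed over the support.
    """

    alpha_min: float
    alpha_max: float
    delta_alpha: float
    f_min: float
    f_max: float
    delta_f: float

    @classmethod
    def from_extrema(cls, alpha_min: float, alpha_max: float,
                     f_min: float, f_max: float) -> "SpectrumParams":
        return cls(alpha_min=alpha_min, alpha_max=alpha_max,
                   delta_alpha=alpha_max - alpha_min,
                   f_min=f_min, f_max=f_max, delta_f=f_max - f_min)


def _as_mass(region) -> np.ndarray:
    if isinstance(region, GrayImage):
        return region.pixels.astype(np.float64)
    arr = np.asarray(region, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("region must be 2D")
    if (arr < 0).any():
        raise ValueError("mass field must be non-negative")
    return arr


def measure(region, eps: int) -> MeasureField:
    """Box mass fractions P(eps, i) of a grayscale region or raw mass field."""
    arr = _as_mass(region)
    if eps < 1:
        raise ValueError("box side must be >= 1")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero region: measure undefined")
    rows = np.arange(0, arr.shape[0], eps)
    cols = np.arange(0, arr.shape[1], eps)
    sums = np.add.reduceat(np.add.reduceat(arr, rows, axis=0), cols, axis=1)
    return MeasureField(box_side=int(eps), p=sums / total)


def mu_weights(field: MeasureField, q: float) -> np.ndarray:
    """Normalized Q-warped box weights mu_i = P_i^Q / sum P_j^Q.

    Computed in log space so extreme Q (|Q| ~ 10) cannot overflow.  Only
    boxes with positive mass participate.
    """
    p = field.positive_masses()
    if p.size == 0:
        raise ValueError("no boxes with positive mass")
    logw = q * np.log(p)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def spectrum(region, q_grid=DEFAULT_Q_GRID, eps_list=DEFAULT_EPS) -> MultifractalSpectrum:
    """Estimate alpha(Q) and f(Q) by regression over box sides.

    With a single box side the quotient form (divide by ln eps) is used as a
    degenerate fallback, with a warning.
    """
    q_grid = np.asarray(sorted(q_grid), dtype=float)
    eps_list = tuple(sorted(set(int(e) for e in eps_list)))
    if len(eps_list) < 1:
        raise ValueError("need at least one box side")
    single = len(eps_list) == 1
    if single:
        warnings.warn("single box side: falling back to the quotient estimator",
                      stacklevel=2)
    log_eps = np.log(np.asarray(eps_list, dtype=float))

    # accumulate sum mu ln P and sum mu ln mu for every (Q, eps)
    a_num = np.empty((q_grid.size, len(eps_list)))
    f_num = np.empty_like(a_num)
    for j, eps in enumerate(eps_list):
        field = measure(region, eps)
        logp = np.log(field.positive_masses())
        for i, q in enumerate(q_grid):
            logw = q * logp
            logw -= logw.max()
            w = np.exp(logw)
            mu = w / w.sum()
            a_num[i, j] = mu @ logp
            nz = mu > 0
            f_num[i, j] = mu[nz] @ np.log(mu[nz])

    alpha = np.empty(q_grid.size)
    f = np.empty(q_grid.size)
    r2a = np.empty(q_grid.size)
    r2f = np.empty(q_grid.size)
    for i in range(q_grid.size):
        if single:
            alpha[i] = a_num[i, 0] / log_eps[0]
            f[i] = f_num[i, 0] / log_eps[0]
            r2a[i] = r2f[i] = np.nan
        else:
            alpha[i], r2a[i] = _slope_r2(log_eps, a_num[i])
            f[i], r2f[i] = _slope_r2(log_eps, f_num[i])
    return MultifractalSpectrum(q=q_grid, alpha=alpha, f=f,
                                r2_alpha=r2a, r2_f=r2f)


def _slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-18 else \
        (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return float(slope), r2


def spectrum_params(s: MultifractalSpectrum) -> SpectrumParams:
    """Extrema of alpha and f over the Q grid and their bandwidths.

    Estimated f values exceeding the support dimension (2 for planar
    measures) are reported as-is; a finite-size estimator can legitimately
    produce them and clamping would hide the bias.
    """
    if s.q.size < 1:
        raise ValueError("empty spectrum")
    return SpectrumParams.from_extrema(
        alpha_min=float(np.nanmin(s.alpha)),
        alpha_max=float(np.nanmax(s.alpha)),
        f_min=float(np.nanmin(s.f)),
        f_max=float(np.nanmax(s.f)),
    )


def average_spectra(spectra) -> MultifractalSpectrum:
    """Pointwise mean of spectra sharing one Q grid (group-level spectrum)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    q0 = spectra[0].q
    for s in spectra[1:]:
        if not np.array_equal(s.q, q0):
            raise ValueError("spectra must share the same Q grid")
    return MultifractalSpectrum(
        q=q0,
        alpha=np.mean([s.alpha for s in spectra], axis=0),
        f=np.mean([s.f for s in spectra], axis=0),
        r2_alpha=np.mean([s.r2_alpha for s in spectra], axis=0),
        r2_f=np.mean([s.r2_f for s in spectra], axis=0),
    )


def cascade_alpha_f(weights, q) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form alpha(Q), f(Q) of a b x b multiplicative cascade.

    tau(Q) = -log_b sum w_i^Q;  alpha = -(sum w^Q ln w)/(ln b * sum w^Q);
    f = Q*alpha - tau.  Useful as an independent oracle for the estimator.
    """
    w = np.asarray(weights, dtype=float)
    b = int(round(np.sqrt(w.size)))
    q = np.atleast_1d(np.asarray(q, dtype=float))
    w = w[w > 0]
    lw = np.log(w)
    s = np.exp(q[:, None] * lw[None, :])  # w^Q
    ssum = s.sum(axis=1)
    tau = -np.log(ssum) / np.log(b)
    alpha = -(s @ lw) / (np.log(b) * ssum)
    f = q * alpha - tau
    return alpha, f
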