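"""Synthetic fixtures with known ground truth for every estimator.

Four generator families:

* Sierpinski-type carpets — exact monofractals of dimension ln m / ln b,
  the oracle for box counting;
* binomial multiplicative cascades — exact multifractal measures with the
  closed-form spectrum tau(Q) = -log_b sum w_i^Q, the oracle for the
  mu-measure spectrum estimator;
* Anderson lattices — i.i.d. site disorder of tunable width W, the oracle
  for IPR localization behavior;
* pseudo-tissue textures — spatially correlated, long-tailed intensity
  fields with a "severity" knob that jointly raises region-level fractal
  dimension, its dispersion, multifractal bandwidth, and <IPR>, emulating
  the control-vs-disease contrast of bright-field tissue micrographs.

Every generator is pure given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage
from .ipr import OpticalLattice
from .thresholding import BinaryImage

_MAX_SIDE = 2048


@dataclass(frozen=True)
class CarpetSpec:
    """Box-fractal carpet: base b, m retained cells per cell, k levels."""

    base: int = 3
    retained: int = 8
    levels: int = 4
    seed: int | None = None  # None -> deterministic center-out retention

    def __post_init__(self) -> None:
        if not (1 <= self.retained <= self.base ** 2):
            raise ValueError("retained cells must be in [1, base^2]")
        if self.base ** self.levels > _MAX_SIDE:
            raise ValueError(f"carpet side {self.base ** self.levels} exceeds {_MAX_SIDE}")

    @property
    def dimension(self) -> float:
        """Analytic box-counting dimension ln m / ln b."""
        return float(np.log(self.retained) / np.log(self.base))


@dataclass(frozen=True)
class CascadeSpec:
    """Multiplicative cascade: b^2 weights summing to 1, k levels."""

    weights: tuple
    levels: int = 6
    seed: int | None = None  # None -> fixed arrangement; else per-cell shuffle

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        b = int(round(np.sqrt(w.size)))
        if b * b != w.size:
            raise ValueError("number of weights must be a perfect square")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if b ** self.levels > _MAX_SIDE:
            raise ValueError(f"cascade side {b ** self.levels} exceeds {_MAX_SIDE}")

    @property
    def base(self) -> int:
        return int(round(np.sqrt(len(self.weights))))


@dataclass(frozen=True)
class PseudoTissueSpec:
    """Pseudo-tissue texture parameters.

    ``severity`` in [0, 1] scales the disorder: it widens the correlated
    background fluctuations, raises the density and intensity of bright
    clumps (mass accumulations) and fattens their intensity tail.  The
    defaults mimic a 480 x 480 bright-field transmission micrograph with a
    mid-gray background.
    """

    size: int = 480
    background: float = 160.0
    field_sigma: float = 25.0            # base texture fluctuation scale
    spectral_exponent: float = 1.5       # power-spectrum slope of the base texture
    patch_exponent: float = 4.0          # spectrum slope of the disease patch fields (smoother)
    accum_gain: float = 0.28             # relative brightening of accumulated patches at severity 1
    loss_gain: float = 0.10              # relative dimming of atrophic patches at severity 1
    clump_density: float = 15.0          # clumps per 480x480 area at severity 0
    clump_amplitude: float = 40.0        # median clump peak height at severity 0
    clump_log_sigma: float = 0.5         # lognormal width of clump peaks at severity 0
    noise_cv: float = 0.06               # pixel-scale relative fluctuation at severity 0
    pore_fraction: float = 0.001         # extreme-pixel (micro-pore) rate at severity 0
    pore_factor: float = 0.12            # intensity multiplier inside a pore pixel
    severity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")
        if self.size < 16:
            raise ValueError("size must be >= 16")


def make_carpet(spec: CarpetSpec | None = None, **kwargs) -> BinaryImage:
    """Generate a b^k x b^k carpet mask.

    Deterministic variant (seed None): at each level every active cell keeps
    the m subcells farthest from the cell center (raster-order ties), which
    reproduces the classical Sierpinski carpet for b=3, m=8.  Random variant:
    each active cell keeps m uniformly chosen subcells.  Either way each
    active cell has exactly m active children, so box counts at construction
    scales are exactly m^level.
    """
    spec = spec or CarpetSpec(**kwargs)
    b, m = spec.base, spec.retained
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None

    if rng is None:
        c = (b - 1) / 2.0
        yy, xx = np.mgrid[0:b, 0:b]
        dist = (yy - c) ** 2 + (xx - c) ** 2
        order = np.argsort(-dist.ravel(), kind="stable")
        cell = np.zeros(b * b, dtype=bool)
        cell[order[:m]] = True
        cell = cell.reshape(b, b)

    mask = np.ones((1, 1), dtype=bool)
    for _ in range(spec.levels):
        s = mask.shape[0]
        if rng is None:
            mask = np.kron(mask, cell)
        else:
            ys, xs = np.nonzero(mask)
            n_active = ys.size
            # m uniform subcells per active cell
            pick = np.argsort(rng.random((n_active, b * b)), axis=1)[:, :m]
            pat = np.zeros((n_active, b * b), dtype=bool)
            pat[np.arange(n_active)[:, None], pick] = True
            out = np.zeros((s, s, b, b), dtype=bool)
            out[ys, xs] = pat.reshape(n_active, b, b)
            mask = out.transpose(0, 2, 1, 3).reshape(s * b, s * b)
    return BinaryImage(pixels=mask.astype(np.uint8))


def make_cascade(spec: CascadeSpec | None = None, **kwargs) -> np.ndarray:
    """Generate the raw (float) measure of a multiplicative cascade.

    Returned as a b^k x b^k array summing to 1, with box masses at every
    construction scale equal to exact products of the weights.  Kept in
    float; quantize to 8 bits only on explicit export (cascade_to_gray),
    since quantization destroys deep-level mass ratios.
    """
    spec = spec or CascadeSpec(**kwargs)
    b = spec.base
    w = np.asarray(spec.weights, dtype=float)
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    field = np.ones((1, 1))
    for _ in range(spec.levels):
        s = field.shape[0]
        if rng is None:
            field = np.kron(field, w.reshape(b, b))
        else:
            # independent arrangement of the same weights in every cell
            blocks = rng.permuted(
                np.broadcast_to(w, (s * s, b * b)).copy(), axis=1)
            blocks = blocks.reshape(s, s, b, b)
            field = field[:, :, None, None] * blocks
            field = field.transpose(0, 2, 1, 3).reshape(s * b, s * b)
    return field


def cascade_to_gray(measure: np.ndarray) -> GrayImage:
    """Linearly rescale a raw cascade measure to the 0-255 grayscale."""
    m = np.asarray(measure, dtype=float)
    top = m.max()
    if top <= 0:
        raise ValueError("measure has no mass")
    return GrayImage(np.round(255.0 * m / top).astype(np.int64))


def make_anderson(L: int, W: float, seed: int | None = 0) -> OpticalLattice:
    """Anderson lattice with i.i.d. site potentials ~ Uniform(-W/2, W/2)."""
    if L < 2:
        raise ValueError("L must be >= 2")
    if W < 0:
        raise ValueError("disorder width W must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.uniform(-W / 2.0, W / 2.0, size=(L, L)) if W > 0 else np.zeros((L, L))
    return OpticalLattice(eps=eps)


def _correlated_field(size: int, spectral_exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std Gaussian field with power spectrum ~ |k|^-beta."""
    kx = np.fft.fftfreq(size)[None, :]
    ky = np.fft.fftfreq(size)[:, None]
    k2 = kx ** 2 + ky ** 2
    k2[0, 0] = (1.0 / size) ** 2  # avoid the DC singularity
    amp = k2 ** (-spectral_exponent / 4.0)
    phase = np.fft.fft2(rng.standard_normal((size, size)))
    field = np.real(np.fft.ifft2(phase * amp))
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def make_pseudo_tissue(spec: PseudoTissueSpec | None = None, **kwargs) -> GrayImage:
    """Pseudo-tissue texture: correlated background, bright clumps, fine noise.

    The image is background + sigma * correlated field + Gaussian clumps with
    lognormal peak intensities + pixel-scale Gaussian noise, clipped to
    [0, 255].  The correlated field emulates smooth tissue-architecture
    variation, the clumps localized mass accumulation, and the pixel-scale
    noise fine-grained density fluctuations.  Every severity-dependent knob
    increases monotonically with severity, so cohorts generated at severity 0
    vs 1 differ in MeanDf (higher), STDDf (higher), spectrum bandwidth
    (wider) and <IPR> (higher) in the disease direction at every window size.
    """
    spec = spec or PseudoTissueSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    s = spec.severity
    size = spec.size

    # Base texture: fine-grained correlated field, so healthy regions
    # self-average to a tight per-region Df distribution.  Disease is patchy:
    # accumulated patches (mass deposition) are relatively brighter, atrophic
    # patches relatively dimmer; both patch fields are much smoother than the
    # base texture (region-sized blobs with soft sigmoid edges), so severity
    # raises the mean of region Df (accumulation dominates) while the
    # accumulation/loss mixture widens its between-region spread.
    def _sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    g = _correlated_field(size, spec.spectral_exponent, rng)
    m_acc = _sig(6.0 * (_correlated_field(size, spec.patch_exponent, rng) - 0.3))
    m_loss = _sig(6.0 * (_correlated_field(size, spec.patch_exponent, rng) - 0.8))
    img = ((spec.background + spec.field_sigma * g)
           * (1.0 + spec.accum_gain * s * m_acc)
           * (1.0 - spec.loss_gain * s * m_loss))

    area_scale = (size / 480.0) ** 2
    density = spec.clump_density * (1.0 + 4.5 * s)
    n_clumps = rng.poisson(density * area_scale)
    amp_scale = spec.clump_amplitude * (1.0 + 1.5 * s)
    log_sigma = spec.clump_log_sigma * (1.0 + 1.2 * s)
    for _ in range(n_clumps):
        cy, cx = rng.uniform(0, size, 2)
        width = rng.uniform(2.0, 6.0)
        amp = amp_scale * rng.lognormal(0.0, log_sigma)
        r = int(np.ceil(3 * width))
        y0, y1 = max(0, int(cy) - r), min(size, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(size, int(cx) + r + 1)
        yy = np.arange(y0, y1)[:, None] - cy
        xx = np.arange(x0, x1)[None, :] - cx
        img[y0:y1, x0:x1] += amp * np.exp(-(yy ** 2 + xx ** 2) / (2 * width ** 2))

    # pixel-scale multiplicative (intensity-proportional) fluctuations: keeps
    # relative heterogeneity alive even inside bright, saturating clumps
    img = np.clip(img, 0, 255)
    cv = spec.noise_cv * (1.0 + 0.8 * s)
    img = img * (1.0 + cv * rng.standard_normal((size, size)))

    # extreme pixels: dark micro-pores whose rate grows with severity; each is
    # a strong isolated scatterer that localizes lattice states at any window
    # size, giving the heavy intensity tail of disordered tissue
    p_pore = spec.pore_fraction + 0.04 * s
    pores = rng.random((size, size)) < p_pore
    img = np.where(pores, img * spec.pore_factor, img)

    # transmission never drops to exactly zero: floor at 1
    return GrayImage(np.clip(np.round(img), 1, 255).astype(np.int64))


def make_cohort(n_images: int, severity: float, seed: int = 0,
                **spec_kwargs) -> list[GrayImage]:
    """A reproducible cohort of pseudo-tissue images at one severity."""
    base = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n_images)
    return [make_pseudo_tissue(PseudoTissueSpec(severity=severity,
                                                seed=int(si), **spec_kwargs))
            for si in base]
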