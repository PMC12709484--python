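"""Tight-binding optical lattices from intensity windows and IPR statistics.

Relative transmission-intensity fluctuations within a window act as site
potentials of an Anderson tight-binding Hamiltonian on the square lattice:

    H = sum_i eps_i |i><i| + t sum_<ij> (|i><j| + |j><i|),
    eps_i = (I_i - Ibar) / Ibar,   t = 1 (energy unit),

with nearest-neighbor hopping and open (hard-wall) boundaries by default.
The inverse participation ratio of a unit-normalized eigenvector,
IPR_k = sum_sites |E_k(site)|^4, is 1/L^2 for a fully extended state and 1
for a delta-localized one; its mean over all L^2 eigenstates, <IPR>, grows
with site disorder and therefore quantifies structural heterogeneity of the
window.

Because a uniform shift of all site potentials cannot change eigenvectors,
the diagonal is centered (mean subtracted) before diagonalization; shift
invariance of every IPR is then exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

DEFAULT_PIXEL_SIZES = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class OpticalLattice:
    """L x L site potentials (units of the hopping amplitude t = 1)."""

    eps: np.ndarray
    t: float = 1.0

    def __post_init__(self) -> None:
        e = np.asarray(self.eps, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1] or e.shape[0] < 2:
            raise ValueError("site potentials must form a square L x L grid, L >= 2")
        if not np.isfinite(e).all():
            raise ValueError("site potentials must be finite")
        object.__setattr__(self, "eps", e)

    @property
    def L(self) -> int:
        return self.eps.shape[0]


@dataclass(frozen=True)
class IPRResult:
    """Pooled <IPR> statistics over all windows of a group at one lattice size."""

    pixel_size: int
    window_values: np.ndarray       # pooled per-window <IPR>
    mean: float
    std: float
    n_windows: int
    image_grids: tuple = ()         # per-image 2D arrays of window <IPR> (colormaps)

    @property
    def mean_normalized(self) -> float:
        """<IPR> x L^2: participation relative to the fully extended limit.

        Raw <IPR> falls like 1/L^2 with lattice size for weakly disordered
        windows; the normalized form isolates the growth of structural
        disorder with window size (larger windows see larger correlated
        intensity fluctuations, hence relatively stronger localization).
        """
        return self.mean * self.pixel_size ** 2


def build_lattice(window: GrayImage, disorder_scale: float = 1.0) -> OpticalLattice:
    """Site potentials eps_i = scale * (I_i - Ibar) / Ibar from a square window.

    The window mean plays the role of the reference intensity I0, so doubling
    all intensities leaves the lattice unchanged.  ``disorder_scale`` is the
    unspecified proportionality between relative intensity and relative
    refractive-index fluctuation; 1 by default.
    """
    px = window.pixels.astype(float)
    if px.shape[0] != px.shape[1] or px.shape[0] < 2:
        raise ValueError("window must be square with side >= 2")
    mean = px.mean()
    if mean <= 0:
        raise ValueError("all-zero window: relative fluctuations undefined")
    return OpticalLattice(eps=disorder_scale * (px - mean) / mean)


def _hop_matrix(L: int, periodic: bool = False) -> np.ndarray:
    """Nearest-neighbor hopping on the L x L square lattice (t = 1)."""
    chain = np.zeros((L, L))
    idx = np.arange(L - 1)
    chain[idx, idx + 1] = chain[idx + 1, idx] = 1.0
    if periodic and L > 2:
        chain[0, L - 1] = chain[L - 1, 0] = 1.0
    eye = np.eye(L)
    return np.kron(eye, chain) + np.kron(chain, eye)


def hamiltonian(lat: OpticalLattice, periodic: bool = False) -> np.ndarray:
    """Dense symmetric L^2 x L^2 tight-binding operator of the lattice."""
    L = lat.L
    h = lat.t * _hop_matrix(L, periodic)
    d = np.arange(L * L)
    h[d, d] += lat.eps.ravel()
    return h


def ipr_states(lat: OpticalLattice, periodic: bool = False) -> np.ndarray:
    """IPR of every eigenstate of the lattice Hamiltonian.

    The diagonal is centered before diagonalization (eigenvectors are
    invariant under a uniform potential shift).  At eps = 0 the spectrum is
    degenerate and per-state IPRs depend on the solver's basis choice inside
    degenerate subspaces; their mean is still well defined.
    """
    h = hamiltonian(lat, periodic)
    d = np.arange(h.shape[0])
    h[d, d] -= h[d, d].mean()
    _, vecs = np.linalg.eigh(h)
    return (vecs ** 4).sum(axis=0)


def mean_ipr(lat: OpticalLattice, periodic: bool = False) -> float:
    """<IPR> = mean of IPR over all L^2 eigenstates."""
    return float(ipr_states(lat, periodic).mean())


def ipr_of_window(window: GrayImage, disorder_scale: float = 1.0,
                  periodic: bool = False) -> float:
    """Per-window <IPR> from its intensity-derived lattice."""
    return mean_ipr(build_lattice(window, disorder_scale), periodic)


def _windows(px: np.ndarray, L: int) -> np.ndarray:
    """Non-overlapping L x L windows of an image as an (n, L, L) stack."""
    nr, nc = px.shape[0] // L, px.shape[1] // L
    cropped = px[:nr * L, :nc * L]
    return (cropped.reshape(nr, L, nc, L).transpose(0, 2, 1, 3)
            .reshape(nr * nc, L, L)), nr, nc


def _batched_mean_ipr(stack: np.ndarray, disorder_scale: float,
                      periodic: bool, max_bytes: float = 2e8) -> np.ndarray:
    """Per-window <IPR> for a stack of windows, vectorized over windows."""
    n, L, _ = stack.shape
    N = L * L
    hop = _hop_matrix(L, periodic)
    means = stack.reshape(n, N).mean(axis=1)
    if (means <= 0).any():
        # zero-transmission windows carry no relative-fluctuation signal
        keep = means > 0
        stack, means, n = stack[keep], means[keep], int(keep.sum())
        if n == 0:
            raise ValueError("every window has zero mean intensity")
    eps = disorder_scale * (stack.reshape(n, N) - means[:, None]) / means[:, None]
    eps -= eps.mean(axis=1, keepdims=True)  # exact shift invariance
    out = np.empty(n)
    chunk = max(1, int(max_bytes / (N * N * 8 * 3)))
    d = np.arange(N)
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        h = np.broadcast_to(hop, (hi - lo, N, N)).copy()
        h[:, d, d] += eps[lo:hi]
        _, vecs = np.linalg.eigh(h)
        out[lo:hi] = (vecs ** 4).sum(axis=1).mean(axis=1)
    return out


def ipr_scan(images, pixel_sizes=DEFAULT_PIXEL_SIZES, disorder_scale: float = 1.0,
             periodic: bool = False) -> dict[int, IPRResult]:
    """<IPR> statistics per lattice size, pooled over windows of all images.

    Each image is tiled into non-overlapping L x L windows; the group mean is
    the mean of per-window <IPR> pooled across images, the STD the sample
    standard deviation over the same pool.  Sizes larger than an image are
    skipped for that image.  Per-image window grids are kept for colormap
    rendering.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    results: dict[int, IPRResult] = {}
    for L in pixel_sizes:
        if L < 2:
            raise ValueError("lattice size must be >= 2")
        pooled = []
        grids = []
        for img in images:
            px = img.pixels.astype(float)
            if min(px.shape) < L:
                continue
            stack, nr, nc = _windows(px, L)
            vals = _batched_mean_ipr(stack, disorder_scale, periodic)
            pooled.append(vals)
            grids.append(vals.reshape(nr, nc))
        if not pooled:
            continue  # size exceeds every image: skipped
        vals = np.concatenate(pooled)
        results[int(L)] = IPRResult(
            pixel_size=int(L), window_values=vals,
            mean=float(vals.mean()),
            std=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            n_windows=int(vals.size), image_grids=tuple(grids))
    return results
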