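import numpy as np
import pytest

from tissuefractal.image_io import GrayImage
from tissuefractal.ipr import (OpticalLattice, _batched_mean_ipr, build_lattice,
                               hamiltonian, ipr_of_window, ipr_scan, ipr_states,
                               mean_ipr)
from tissuefractal.synthetic import make_anderson


class TestBuildLattice:
    def test_constant_window_is_ordered(self):
        lat = build_lattice(GrayImage(np.full((4, 4), 150)))
        np.testing.assert_allclose(lat.eps, 0.0)

    def test_relative_fluctuation_arithmetic(self):
        # mean 75: three sites at -1/3, the bright site at +1
        lat = build_lattice(GrayImage(np.array([[50, 50], [50, 150]])))
        np.testing.assert_allclose(lat.eps,
                                   [[-1 / 3, -1 / 3], [-1 / 3, 1.0]])

    def test_intensity_scale_invariance(self):
        px = np.array([[10, 20], [30, 40]])
        a = build_lattice(GrayImage(px))
        b = build_lattice(GrayImage(2 * px))
        np.testing.assert_allclose(a.eps, b.eps)

    def test_all_zero_window_rejected(self):
        with pytest.raises(ValueError):
            build_lattice(GrayImage(np.zeros((4, 4), dtype=np.uint8)))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            build_lattice(GrayImage(np.full((2, 4), 10)))


class TestHamiltonian:
    def test_l2_ordered_spectrum(self):
        h = hamiltonian(OpticalLattice(np.zeros((2, 2))))
        np.testing.assert_allclose(np.linalg.eigvalsh(h), [-2, 0, 0, 2],
                                   atol=1e-12)

    def test_l3_ordered_tensor_sum_spectrum(self):
        # open-chain modes 2cos(k pi/4), tensor-summed over x and y
        h = hamiltonian(OpticalLattice(np.zeros((3, 3))))
        chain = 2 * np.cos(np.arange(1, 4) * np.pi / 4)
        expected = np.sort((chain[:, None] / 2 * 0 + chain[:, None]
                            + chain[None, :]).ravel())
        np.testing.assert_allclose(np.linalg.eigvalsh(h), expected, atol=1e-12)

    def test_symmetric(self, rng):
        lat = OpticalLattice(rng.normal(size=(5, 5)))
        h = hamiltonian(lat)
        np.testing.assert_array_equal(h, h.T)

    def test_periodic_adds_wraparound_bonds(self):
        open_h = hamiltonian(OpticalLattice(np.zeros((4, 4))))
        per_h = hamiltonian(OpticalLattice(np.zeros((4, 4))), periodic=True)
        assert per_h.sum() > open_h.sum()


class TestIPR:
    @pytest.mark.parametrize("W", [0.0, 1.0, 10.0])
    def test_bounds(self, W):
        lat = make_anderson(8, W, seed=5)
        vals = ipr_states(lat)
        assert (vals >= 1 / 64 - 1e-12).all() and (vals <= 1 + 1e-12).all()

    def test_potential_shift_invariance(self):
        # ordered lattice: constant shift centers away exactly (bitwise)
        ordered = OpticalLattice(np.zeros((6, 6)))
        shifted_ordered = OpticalLattice(np.full((6, 6), 7.5))
        np.testing.assert_array_equal(ipr_states(ordered),
                                      ipr_states(shifted_ordered))
        # disordered lattice: invariant up to centering roundoff
        lat = make_anderson(6, 3.0, seed=2)
        shifted = OpticalLattice(lat.eps + 7.5)
        np.testing.assert_allclose(ipr_states(lat), ipr_states(shifted),
                                   atol=1e-13)

    def test_ordered_lattice_near_minimal(self, rng):
        # W=0 gives the smallest <IPR> among disordered configurations
        base = mean_ipr(OpticalLattice(np.zeros((8, 8))))
        disordered = [mean_ipr(OpticalLattice(rng.normal(0, 2.0, (8, 8))))
                      for _ in range(25)]
        assert all(d > base for d in disordered)

    def test_disorder_monotonicity_small(self):
        means = []
        for W in (0.5, 2.0, 5.0, 10.0):
            vals = [mean_ipr(make_anderson(8, W, seed=s)) for s in range(60)]
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_window_of_uniform_intensity(self):
        # ordered lattice: every state extended-ish, <IPR> well below 1
        val = ipr_of_window(GrayImage(np.full((8, 8), 90)))
        assert 1 / 64 <= val < 0.2


class TestIPRScan:
    def test_constant_image_zero_std(self):
        img = GrayImage(np.full((32, 32), 120))
        res = ipr_scan([img], (4, 8))
        for L in (4, 8):
            assert res[L].std == pytest.approx(0.0, abs=1e-12)
            assert res[L].n_windows == (32 // L) ** 2

    def test_oversized_lattice_skipped(self):
        img = GrayImage(np.full((16, 16), 120))
        res = ipr_scan([img], (8, 32))
        assert 8 in res and 32 not in res

    def test_batched_matches_per_window(self, rng):
        img = GrayImage(rng.integers(50, 250, size=(16, 16)))
        res = ipr_scan([img], (8,))
        singles = [ipr_of_window(GrayImage(img.pixels[r * 8:(r + 1) * 8,
                                                      c * 8:(c + 1) * 8]))
                   for r in range(2) for c in range(2)]
        np.testing.assert_allclose(sorted(res[8].window_values),
                                   sorted(singles), atol=1e-10)

    def test_normalized_mean_grows_with_window_size(self, rng):
        # participation relative to the extended limit grows with L on
        # spatially correlated heterogeneity (larger windows, larger
        # relative fluctuations)
        from tissuefractal.synthetic import PseudoTissueSpec, make_pseudo_tissue
        img = make_pseudo_tissue(PseudoTissueSpec(size=128, severity=0.5, seed=4))
        res = ipr_scan([img], (2, 4, 8, 16, 32))
        norms = [res[L].mean_normalized for L in (2, 4, 8, 16, 32)]
        assert all(b >= a for a, b in zip(norms, norms[1:]))

    def test_disorder_scale_raises_ipr(self, rng):
        img = GrayImage(rng.integers(80, 180, size=(16, 16)))
        weak = ipr_scan([img], (16,), disorder_scale=1.0)[16].mean
        strong = ipr_scan([img], (16,), disorder_scale=10.0)[16].mean
        assert strong > weak
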