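import numpy as np
import pytest

from tissuefractal.image_io import GrayImage
from tissuefractal.multifractal import (MeasureField, SpectrumParams,
                                        average_spectra, cascade_alpha_f,
                                        measure, mu_weights, spectrum,
                                        spectrum_params)
from tissuefractal.synthetic import CascadeSpec, make_cascade

POW2_EPS = (2, 4, 8, 16)


class TestMeasure:
    def test_constant_region_quarters(self):
        field = measure(GrayImage(np.full((8, 8), 100)), 4)
        np.testing.assert_allclose(field.p, 0.25)

    def test_concentrated_mass(self):
        px = np.zeros((8, 8), dtype=np.uint8)
        px[0, 0] = 200
        field = measure(GrayImage(px), 4)
        assert field.p[0, 0] == 1.0 and field.p.sum() == 1.0

    def test_all_zero_region_rejected(self):
        with pytest.raises(ValueError):
            measure(GrayImage(np.zeros((8, 8), dtype=np.uint8)), 4)

    @pytest.mark.parametrize("eps", [2, 4, 6, 10, 12])
    def test_normalization(self, noisy_image, eps):
        assert measure(noisy_image, eps).p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cascade_box_masses_are_weight_products(self):
        # at one subdivision level the four box masses are exactly the weights
        m = make_cascade(CascadeSpec(weights=(0.4, 0.3, 0.2, 0.1), levels=5))
        field = measure(m, 16)  # 32x32 measure -> 2x2 boxes = level-1 cells
        np.testing.assert_allclose(sorted(field.p.ravel()), [0.1, 0.2, 0.3, 0.4],
                                   atol=1e-12)


class TestMuWeights:
    def test_q_zero_uniform_over_occupied(self):
        field = MeasureField(box_side=2, p=np.array([[0.5, 0.3], [0.2, 0.0]]))
        np.testing.assert_allclose(mu_weights(field, 0.0), 1 / 3)

    def test_q_one_identity(self):
        field = MeasureField(box_side=2, p=np.array([[0.5, 0.3], [0.2, 0.0]]))
        np.testing.assert_allclose(mu_weights(field, 1.0), [0.5, 0.3, 0.2])

    def test_q_ten_direct_arithmetic(self):
        field = MeasureField(box_side=2, p=np.array([[0.9, 0.1]]))
        w = np.array([0.9 ** 10, 0.1 ** 10])
        np.testing.assert_allclose(mu_weights(field, 10.0), w / w.sum(), rtol=1e-12)

    @pytest.mark.parametrize("q", [-10.0, -1.0, 0.0, 2.5, 10.0])
    def test_normalized_for_extreme_q(self, noisy_image, q):
        field = measure(noisy_image, 4)
        mu = mu_weights(field, q)
        assert mu.sum() == pytest.approx(1.0, abs=1e-12)
        assert (mu >= 0).all()


class TestSpectrum:
    def test_uniform_region_is_monofractal_plane(self):
        s = spectrum(GrayImage(np.full((64, 64), 200)), eps_list=POW2_EPS)
        np.testing.assert_allclose(s.alpha, 2.0, atol=1e-9)
        np.testing.assert_allclose(s.f, 2.0, atol=1e-9)
        assert spectrum_params(s).delta_alpha == pytest.approx(0.0, abs=1e-9)

    def test_cascade_matches_closed_form(self, cascade_04):
        s = spectrum(cascade_04, eps_list=POW2_EPS)
        a_true, f_true = cascade_alpha_f((0.4, 0.3, 0.2, 0.1), s.q)
        np.testing.assert_allclose(s.alpha, a_true, atol=0.02)
        np.testing.assert_allclose(s.f, f_true, atol=0.02)

    def test_cascade_extreme_q_limits(self, cascade_04):
        s = spectrum(cascade_04, eps_list=POW2_EPS)
        assert s.alpha[s.q == 10.0][0] == pytest.approx(-np.log2(0.4), abs=0.05)
        assert s.alpha[s.q == -10.0][0] == pytest.approx(-np.log2(0.1), abs=0.05)

    def test_alpha_nonincreasing_in_q(self, cascade_04):
        s = spectrum(cascade_04, eps_list=POW2_EPS)
        assert (np.diff(s.alpha) <= 1e-9).all()

    def test_f_maximal_at_q_zero(self, noisy_image):
        s = spectrum(noisy_image, eps_list=(2, 4, 6, 10, 12))
        f0 = s.f[s.q == 0.0][0]
        assert (s.f <= f0 + 1e-6).all()

    def test_shuffle_invariance_of_exact_cascade(self):
        w = (0.4, 0.3, 0.2, 0.1)
        plain = spectrum(make_cascade(CascadeSpec(weights=w, levels=5)),
                         eps_list=(2, 4, 8))
        shuffled = spectrum(make_cascade(CascadeSpec(weights=w, levels=5, seed=9)),
                            eps_list=(2, 4, 8))
        np.testing.assert_allclose(plain.alpha, shuffled.alpha, atol=1e-9)
        np.testing.assert_allclose(plain.f, shuffled.f, atol=1e-9)

    def test_single_eps_falls_back_with_warning(self, cascade_04):
        with pytest.warns(UserWarning):
            s = spectrum(cascade_04, eps_list=(8,))
        assert np.isfinite(s.alpha).all()

    def test_bandwidth_broadens_with_weight_disparity(self):
        # disparity = wmax/wmin, the asymptotic bandwidth log_b(wmax/wmin)
        weight_sets = [(0.25, 0.25, 0.25, 0.25), (0.3, 0.25, 0.25, 0.2),
                       (0.4, 0.3, 0.2, 0.1), (0.7, 0.1, 0.1, 0.1)]
        widths = []
        for w in weight_sets:
            s = spectrum(make_cascade(CascadeSpec(weights=w, levels=6)),
                         eps_list=POW2_EPS)
            widths.append(spectrum_params(s).delta_alpha)
        assert all(b > a for a, b in zip(widths, widths[1:]))


class TestSpectrumParams:
    def test_table_arithmetic(self):
        control = SpectrumParams.from_extrema(1.0013, 1.0334, 0.862171, 1.015763)
        assert control.delta_alpha == pytest.approx(0.0321, abs=1e-12)
        assert control.delta_f == pytest.approx(0.153592, abs=1e-12)

    def test_single_point_spectrum_zero_widths(self):
        from tissuefractal.multifractal import MultifractalSpectrum
        s = MultifractalSpectrum(q=np.array([0.0]), alpha=np.array([1.7]),
                                 f=np.array([1.9]), r2_alpha=np.array([1.0]),
                                 r2_f=np.array([1.0]))
        p = spectrum_params(s)
        assert p.delta_alpha == 0.0 and p.delta_f == 0.0

    def test_average_spectra_pointwise_mean(self, cascade_04):
        s = spectrum(cascade_04, eps_list=POW2_EPS)
        avg = average_spectra([s, s])
        np.testing.assert_allclose(avg.alpha, s.alpha)
        with pytest.raises(ValueError):
            average_spectra([])
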