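"""Decay model, IRF, binning, intensity and per-pixel fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import omicm as om
from omicm.decay import BiexpDecayModel


class TestIRF:
    def test_gaussian_kernel_is_normalized_and_unimodal(self, spec1px):
        irf = om.gaussian_irf(260.0, spec1px)
        assert irf.kernel.sum() == pytest.approx(1.0, abs=1e-12)
        peak = irf.peak_bin
        assert np.all(np.diff(irf.kernel[: peak + 1]) >= 0)
        assert np.all(np.diff(irf.kernel[peak:]) <= 0)

    def test_narrow_fwhm_degenerates_to_single_bin_delta(self, spec1px):
        irf = om.gaussian_irf(0.01, spec1px)  # 0.01 ps << 48.8 ps bin
        assert irf.kernel.max() == pytest.approx(1.0, abs=1e-9)

    def test_half_maximum_crossings_separated_by_fwhm(self):
        # evaluate on a 10x finer time grid than the standard acquisition
        fine = om.AcquisitionSpec(n_bins=2560)
        irf = om.gaussian_irf(260.0, fine)
        k = irf.kernel
        above = np.nonzero(k >= k.max() / 2)[0]
        width_ps = (above[-1] - above[0] + 1) * fine.bin_width_ns * 1e3
        assert width_ps == pytest.approx(260.0, rel=0.05)

    def test_invalid_fwhm_rejected(self, spec1px):
        with pytest.raises(ValueError):
            om.gaussian_irf(-1.0, spec1px)


class TestModelDecay:
    def test_single_component_delta_irf_is_pure_exponential(self, spec1px):
        y = om.model_decay(2.0, 3.0, 1.0, 1e4, 0.0, om.delta_irf(spec1px), spec1px)
        t = spec1px.time_axis()
        ratio = y / np.exp(-t / 2.0)
        assert np.allclose(ratio, ratio[0])

    def test_zero_amplitude_gives_constant_background(self, spec1px, irf260):
        y = om.model_decay(0.5, 2.5, 0.7, 0.0, 3.5, irf260, spec1px)
        assert np.allclose(y, 3.5)

    def test_bin_sum_equals_amplitude_with_delta_irf(self, spec1px):
        # window/4 = 3.125 ns tail: truncation below 1%
        y = om.model_decay(0.5, 3.0, 0.6, 1e4, 0.0, om.delta_irf(spec1px), spec1px)
        assert y.sum() == pytest.approx(1e4, rel=0.01)

    def test_linear_in_amplitude_and_background(self, spec1px, irf260):
        a = om.model_decay(0.5, 2.5, 0.7, 1e3, 2.0, irf260, spec1px)
        b = om.model_decay(0.5, 2.5, 0.7, 2e3, 4.0, irf260, spec1px)
        assert np.allclose(2 * a, b)


class TestBinning:
    def test_uniform_cube_interior_is_nine_corner_is_four(self, small_spec):
        cube = om.DecayCube(
            np.ones((small_spec.height, small_spec.width, small_spec.n_bins), int),
            small_spec,
        )
        binned = om.bin_3x3(cube)
        assert np.all(binned.counts[5, 5] == 9)
        assert np.all(binned.counts[0, 0] == 4)
        assert np.all(binned.counts[0, 5] == 6)

    def test_matches_bruteforce_neighbourhood_sum(self):
        rng = np.random.default_rng(42)
        spec = om.AcquisitionSpec(width=7, height=6, n_bins=5)
        counts = rng.integers(0, 20, size=(6, 7, 5))
        binned = om.bin_3x3(om.DecayCube(counts, spec))
        for r in range(6):
            for c in range(7):
                block = counts[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2]
                assert np.array_equal(binned.counts[r, c], block.sum(axis=(0, 1)))


class TestIntensity:
    def test_zero_cube_gives_zero_image(self, small_spec):
        cube = om.DecayCube(
            np.zeros((small_spec.height, small_spec.width, small_spec.n_bins), int),
            small_spec,
        )
        assert not om.intensity_image(cube).any()

    def test_single_photon_appears_once(self):
        spec = om.AcquisitionSpec(width=4, height=3, n_bins=8)
        counts = np.zeros((3, 4, 8), int)
        counts[1, 2, 5] = 1
        img = om.intensity_image(om.DecayCube(counts, spec))
        assert img[1, 2] == 1 and img.sum() == 1

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(1)
        spec = om.AcquisitionSpec(width=5, height=5, n_bins=16)
        counts = rng.poisson(3.0, size=(5, 5, 16))
        cube = om.DecayCube(counts, spec)
        assert om.intensity_image(cube).sum() == counts.sum()


class TestTauMean:
    @pytest.mark.parametrize(
        "a1,t1,t2,expected",
        [(1.0, 0.4, 3.0, 0.4), (0.5, 1.0, 3.0, 2.0), (0.7, 0.5, 2.5, 1.1)],
    )
    def test_known_values(self, a1, t1, t2, expected):
        assert om.tau_mean(a1, t1, t2) == pytest.approx(expected)

    @given(
        a1=st.floats(0, 1),
        t1=st.floats(0.05, 1.5),
        gap=st.floats(0.0, 5.0),
    )
    def test_bracketed_by_component_lifetimes(self, a1, t1, gap):
        t2 = t1 + gap
        tm = om.tau_mean(a1, t1, t2)
        assert min(t1, t2) - 1e-12 <= tm <= max(t1, t2) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            om.tau_mean(1.2, 0.5, 2.5)
        with pytest.raises(ValueError):
            om.tau_mean(0.5, -0.5, 2.5)


class TestFitPixel:
    def test_recovers_truth_at_high_photon_count(self, spec1px):
        # generation parameters are the oracle
        irf = om.delta_irf(spec1px)
        expected = om.model_decay(0.5, 2.5, 0.7, 1e5, 0.0, irf, spec1px)
        y = np.random.default_rng(5).poisson(expected)
        # ideal delta response: no instrument alignment to fit
        fit = om.fit_pixel(y, irf, spec1px, om.FitOptions(fit_shift=False))
        assert fit.valid
        assert fit.tau1_ns == pytest.approx(0.5, rel=0.05)
        assert fit.tau2_ns == pytest.approx(2.5, rel=0.05)
        assert fit.alpha1 == pytest.approx(0.7, abs=0.05)

    def test_noiseless_single_exponential_tau_m(self, spec1px):
        irf = om.delta_irf(spec1px)
        y = om.model_decay(1.0, 1.0, 1.0, 1e5, 0.0, irf, spec1px)
        fit = om.fit_pixel(y, irf, spec1px, om.FitOptions(fit_shift=False))
        assert fit.valid
        assert fit.tau_m_ns == pytest.approx(1.0, rel=0.01)

    def test_all_zero_decay_marked_invalid_not_error(self, spec1px, irf260):
        fit = om.fit_pixel(np.zeros(spec1px.n_bins), irf260, spec1px)
        assert not fit.valid

    def test_shape_mismatch_raises(self, spec1px, irf260):
        with pytest.raises(ValueError):
            om.fit_pixel(np.zeros(10), irf260, spec1px)

    def test_fraction_normalization_and_lifetime_ordering(self, spec1px, irf260):
        rng = np.random.default_rng(3)
        for seed in range(5):
            expected = om.model_decay(0.6, 1.4, 0.4, 2e4, 1.0, irf260, spec1px)
            fit = om.fit_pixel(rng.poisson(expected), irf260, spec1px)
            assert fit.valid
            assert fit.alpha1 + fit.alpha2 == pytest.approx(1.0, abs=1e-9)
            assert fit.tau1_ns <= fit.tau2_ns
            assert (
                min(fit.tau1_ns, fit.tau2_ns)
                <= fit.tau_m_ns
                <= max(fit.tau1_ns, fit.tau2_ns)
            )

    def test_results_object_reports_uncertainties_and_summary(self, spec1px, irf260):
        expected = om.model_decay(0.5, 2.5, 0.7, 1e5, 0.0, irf260, spec1px)
        y = np.random.default_rng(9).poisson(expected)
        res = BiexpDecayModel(y, irf260, spec1px).fit()
        se = res.bse()
        assert 0 < se["tau2_ns"] < 0.5
        # approximate 4-sigma sanity band around truth
        assert abs(res.tau2_ns - 2.5) < 4 * se["tau2_ns"] + 1e-6
        text = res.summary()
        assert "tau2_ns" in text and "reduced chi2" in text
        assert np.all(res.predict() >= 0)


class TestFitImage:
    def test_background_only_cube_has_no_valid_pixels(self, small_spec, irf260):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.05, size=(48, 48, 128))
        pmap = om.fit_image(om.DecayCube(counts, small_spec), irf260)
        assert not pmap.valid.any()

    def test_single_cell_field_valid_fraction_and_median_tau_m(self, small_spec):
        masks = om.make_cell_masks(1, small_spec, seed=3, cell_radius_px=10)
        lab = int(masks.labels[0])
        truth_cell = om.DecayTruth(0.5, 2.5, 0.7)
        truth = om.SimGroundTruth("f0", "g", {lab: {"NADH": truth_cell}})
        cube = om.render_decay_cube(masks, truth, small_spec, seed=11)
        irf = om.gaussian_irf(260.0, small_spec)
        pmap = om.fit_image(cube, irf, pixel_mask=masks.whole_cell)
        cell = masks.whole_cell == lab
        assert pmap.valid[cell].mean() >= 0.95
        med = np.nanmedian(pmap.tau_m_ns[cell & pmap.valid])
        assert med == pytest.approx(truth_cell.tau_m_ns, rel=0.05)
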