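from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import ndtr

import penumbra as pn
from penumbra.errors import UndefinedMetricError

from conftest import EXIT_RADIUS, MAG, SOURCE_HEIGHT


def closed_form_crossings(fwhm: float, level: float) -> tuple[float, float]:
    """Independent oracle: right-side crossing positions of the single-aperture
    closed-form profile at a fraction ``level`` of its actual peak."""
    sigma = pn.sigma_from_fwhm(fwhm)
    sp = (MAG - 1.0) * sigma
    mra = MAG * EXIT_RADIUS

    def f(r):
        return ndtr((mra - r) / sp) - ndtr((-mra - r) / sp)

    peak = f(0.0)
    return brentq(lambda r: f(r) - level * peak, 0.0, 4.0 * mra), peak


class TestNormalize:
    def test_peak_becomes_one(self, single_aperture_profile):
        n = pn.normalize(single_aperture_profile)
        assert n.peak == 1.0
        assert n.normalized

    def test_idempotent_and_shape_preserving(self, single_aperture_profile):
        n1 = pn.normalize(single_aperture_profile)
        n2 = pn.normalize(n1)
        assert np.array_equal(n1.values, n2.values)
        v = single_aperture_profile.values
        mask = v > 0
        ratio = n1.values[mask] / v[mask]
        assert np.allclose(ratio, ratio[0])

    def test_all_zero_rejected(self):
        p = pn.Profile(np.arange(5) * 0.1, np.zeros(5))
        with pytest.raises(UndefinedMetricError):
            pn.normalize(p)


class TestFwhm:
    def test_ideal_top_hat(self, top_hat):
        assert pn.fwhm(top_hat) == pytest.approx(4.0, abs=1e-9)

    def test_single_aperture_erf_profile(self, single_aperture_profile):
        # symmetric erf edges cross 50% near +/- M*Ra = 2.0 once the plateau
        # is reached; the finite peak (0.9898 of plateau) nudges it outward
        r50, _ = closed_form_crossings(1.5, 0.5)
        assert pn.fwhm(single_aperture_profile) == pytest.approx(2 * r50, abs=0.01)
        assert pn.fwhm(single_aperture_profile) == pytest.approx(4.0, abs=0.05)

    @given(scale=st.floats(0.1, 50))
    def test_scale_invariance(self, scale, single_aperture_profile):
        scaled = single_aperture_profile.scaled(scale)
        assert pn.fwhm(scaled) == pytest.approx(pn.fwhm(single_aperture_profile), rel=1e-12)

    def test_uncrossed_level_rejected(self):
        r = 0.1 * np.arange(-20, 21)
        v = np.full(r.size, 3.0)  # flat: never drops below 50%
        with pytest.raises(UndefinedMetricError):
            pn.fwhm(pn.Profile(r, v))


class TestPenumbra:
    def test_linear_ramp(self):
        # ramp from peak to zero over width w: 20-80% distance is 0.6 w
        r = 0.1 * np.arange(0, 61)
        w = 3.0
        v = np.clip(1.0 - (r - 1.0) / w, 0.0, 1.0)
        p = pn.Profile(r, v)
        assert pn.penumbra(p, "right") == pytest.approx(0.6 * w, abs=1e-9)

    def test_single_aperture_matches_closed_form_crossings(self, single_aperture_profile):
        r80, _ = closed_form_crossings(1.5, 0.8)
        r20, _ = closed_form_crossings(1.5, 0.2)
        exact = r20 - r80  # 1.2938: thresholds relative to the actual peak
        for side in ("left", "right"):
            assert pn.penumbra(single_aperture_profile, side) == pytest.approx(exact, rel=5e-3)
        # the plateau-relative approximation 1.6832*(M-1)*sigma is ~1.3% high
        approx = 1.6832 * (MAG - 1.0) * pn.sigma_from_fwhm(1.5)
        assert pn.penumbra(single_aperture_profile, "right") == pytest.approx(approx, rel=2e-2)

    def test_symmetric_system_sides_agree(self, single_aperture_profile):
        pl = pn.penumbra(single_aperture_profile, "left")
        pr = pn.penumbra(single_aperture_profile, "right")
        assert abs(pl - pr) < single_aperture_profile.step

    @given(scale=st.floats(0.1, 50))
    def test_scale_invariance(self, scale, single_aperture_profile):
        scaled = single_aperture_profile.scaled(scale)
        assert pn.penumbra(scaled, "right") == pytest.approx(
            pn.penumbra(single_aperture_profile, "right"), rel=1e-12
        )


class TestPeakRatio:
    def test_identity_and_linearity(self, single_aperture_profile):
        a = single_aperture_profile
        assert pn.peak_ratio(a, a) == 1.0
        assert pn.peak_ratio(a, a.scaled(2.0)) == pytest.approx(0.5)

    def test_clipped_source_lowers_peak(self, gaussian_source, geom, exit_aperture):
        src = replace(gaussian_source, normalization="total")
        open_profile = pn.integrate_profile(src, [exit_aperture], geom)
        tight = pn.Aperture(0.6, 407.0)  # trims the spot tails upstream
        clipped = pn.integrate_profile(src, [exit_aperture, tight], geom)
        assert pn.peak_ratio(open_profile, clipped) > 1.0

    def test_normalized_inputs_rejected(self, single_aperture_profile):
        n = pn.normalize(single_aperture_profile)
        with pytest.raises(UndefinedMetricError):
            pn.peak_ratio(n, single_aperture_profile)


class TestDetectorConvolve:
    def test_one_grid_step_window_is_identity(self, single_aperture_profile):
        out = pn.detector_convolve(single_aperture_profile, single_aperture_profile.step)
        assert np.abs(out.values - single_aperture_profile.values).max() < 1e-12

    def test_constant_profile_unchanged(self):
        p = pn.Profile(0.1 * np.arange(0, 41), np.full(41, 2.5))
        out = pn.detector_convolve(p, 1.5)
        assert np.allclose(out.values, 2.5, rtol=1e-12)

    def test_step_edge_becomes_ramp(self, top_hat):
        w = 1.0
        out = pn.detector_convolve(top_hat, w)
        # convolving a step with a top-hat gives a linear edge of width w
        assert pn.penumbra(out, "right") == pytest.approx(0.6 * w, abs=0.02)

    @given(w=st.floats(0.15, 3.0))
    def test_widens_penumbra(self, w, single_aperture_profile):
        base = pn.penumbra(single_aperture_profile, "right")
        out = pn.detector_convolve(single_aperture_profile, w)
        assert pn.penumbra(out, "right") >= base - 1e-9

    def test_window_wider_than_span_rejected(self, top_hat):
        with pytest.raises(ValueError):
            pn.detector_convolve(top_hat, 100.0)

    def test_measurement_emulation_rounds_profile(self, collimator4):
        # a 1.5 mm diode widens the apparent penumbra of the 4 mm field
        src, aps, geom = collimator4.config.build()
        p = pn.integrate_profile(src, aps, geom)
        emulated = pn.detector_convolve(p, 1.5)
        assert pn.penumbra(emulated, "right") > pn.penumbra(p, "right")
        assert pn.fwhm(emulated) == pytest.approx(pn.fwhm(p), abs=0.1)


class TestCompareProfiles:
    def test_self_comparison_is_exactly_zero(self, single_aperture_profile):
        rep = pn.compare_profiles(single_aperture_profile, single_aperture_profile)
        assert rep.fwhm_percent_diff == 0.0
        assert rep.max_abs_diff == 0.0
        assert rep.mean_abs_diff == 0.0

    @pytest.mark.parametrize(
        "ref,other,expected",
        [(25.56, 24.5, 4.147), (25.56, 24.92, 2.504)],
    )
    def test_fwhm_percent_difference_pairs(self, ref, other, expected):
        # reported unrounded: (25.56-24.5)/25.56 = 4.147%, not the rounded 4.16%
        assert pn.percent_difference(ref, other) == pytest.approx(expected, abs=1e-3)

    def test_non_overlapping_grids_rejected(self):
        a = pn.Profile(0.1 * np.arange(0, 11), np.linspace(1, 0.5, 11))
        b = pn.Profile(0.1 * np.arange(50, 61), np.linspace(1, 0.5, 11))
        with pytest.raises(ValueError):
            pn.compare_profiles(a, b)

    def test_interpolated_comparison(self, gaussian_source, exit_aperture):
        geom_a = pn.BeamlineGeometry(SOURCE_HEIGHT, -12.0, 12.0, 0.1)
        geom_b = pn.BeamlineGeometry(SOURCE_HEIGHT, -12.0, 12.0, 0.05)
        a = pn.integrate_profile(gaussian_source, [exit_aperture], geom_a)
        b = pn.integrate_profile(gaussian_source, [exit_aperture], geom_b)
        rep = pn.compare_profiles(a, b)
        assert rep.max_abs_diff < 0.01
        assert rep.fwhm_percent_diff < 0.5
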