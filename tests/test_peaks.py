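"""Collagen/IFC peak fitting, azimuthal orientation fits, order ratios."""

import math

import numpy as np
import pytest

import saxsdic as sx
from saxsdic.geometry import AZIMUTHAL_CHI, Profile1D
from saxsdic.peaks import SQRT2PI


def gauss(q, amp, center, sigma):
    return amp * np.exp(-0.5 * ((q - center) / sigma) ** 2)


class TestCollagenFit:
    def test_worked_example_d_period(self, radial_profile_factory):
        """A 5th-order peak at q05 = 0.4812 must give D = 10*pi/q05 = 65.29 nm."""
        prof = radial_profile_factory(
            lambda q: gauss(q, 12.0, 0.4812, 0.003) + 30.0 * np.exp(-q * 6.0))
        res = sx.fit_collagen(prof)
        assert res.fit.converged
        assert res.D == pytest.approx(10 * math.pi / 0.4812, abs=5e-3)
        assert round(res.D, 2) == 65.29

    def test_exact_model_recovery_zero_background(self, radial_profile_factory):
        prof = radial_profile_factory(lambda q: gauss(q, 8.0, 0.4833, 0.003))
        res = sx.fit_collagen(prof)
        assert res.fit.center == pytest.approx(0.4833, abs=1e-5)
        assert res.I_c == pytest.approx(8.0 * 0.003 * SQRT2PI, rel=1e-4)
        assert res.plausible

    def test_poisson_replicates_unbiased(self, radial_profile_factory):
        """Mean recovered D over noisy replicates stays within 0.02 nm."""
        true_D = 65.0
        center = 10 * math.pi / true_D
        rng = np.random.default_rng(11)
        amp, snr = 400.0, 20.0
        ds = []
        for _ in range(200):
            prof = radial_profile_factory(
                lambda q: np.maximum(
                    gauss(q, amp, center, 0.004) + 5 * amp / snr ** 2 +
                    rng.normal(0.0, amp / snr, q.size), 0.0))
            res = sx.fit_collagen(prof)
            if res.fit.converged:
                ds.append(res.D)
        assert len(ds) > 190
        assert abs(np.mean(ds) - true_D) < 0.02

    def test_background_robustness(self, radial_profile_factory):
        """Doubling the diffuse background moves D by less than 0.01 nm."""
        def model(bg):
            return lambda q: gauss(q, 10.0, 0.4830, 0.0035) + bg * np.exp(-q * 6.0)
        d1 = sx.fit_collagen(radial_profile_factory(model(20.0))).D
        d2 = sx.fit_collagen(radial_profile_factory(model(40.0))).D
        assert abs(d1 - d2) < 0.01

    def test_linear_background_variant(self, radial_profile_factory):
        prof = radial_profile_factory(
            lambda q: gauss(q, 10.0, 0.4820, 0.003) + 5.0 - 4.0 * q)
        res = sx.fit_collagen(prof, background="linear")
        assert res.fit.center == pytest.approx(0.4820, abs=1e-5)

    def test_degenerate_profile_flagged_not_raised(self, radial_profile_factory):
        prof = radial_profile_factory(lambda q: np.full_like(q, 7.0))
        res = sx.fit_collagen(prof)
        assert not res.fit.converged
        assert math.isnan(res.D)

    def test_window_outside_support_raises(self, radial_profile_factory):
        prof = radial_profile_factory(lambda q: np.ones_like(q))
        with pytest.raises(ValueError):
            sx.fit_collagen(prof, window=(0.9, 1.1))


class TestIFCFit:
    @pytest.mark.parametrize("center, expected_d", [
        (0.1257, 4 * math.pi / 0.1257),   # ~100 nm
        (4 * math.pi / 88.0, 88.0),       # q = 0.142800
    ])
    def test_spacing_from_center(self, radial_profile_factory, center, expected_d):
        prof = radial_profile_factory(
            lambda q: gauss(q, 5.0, center, 0.012) + 20 * np.exp(-q * 6.0),
            q_lo=0.10, q_hi=0.18, n_bins=80)
        res = sx.fit_ifc(prof, window=(0.11, 0.17))
        assert res.fit.converged
        assert res.D_ifc == pytest.approx(expected_d, rel=2e-3)
        assert res.plausible

    def test_flat_profile_flagged(self, radial_profile_factory):
        prof = radial_profile_factory(lambda q: np.full_like(q, 3.0),
                                      q_lo=0.10, q_hi=0.18, n_bins=60)
        res = sx.fit_ifc(prof, window=(0.115, 0.15))
        assert not res.fit.converged
        assert math.isnan(res.D_ifc)


def chi_profile(model, n_bins=72):
    grid = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    return Profile1D(AZIMUTHAL_CHI, grid, model(grid),
                     np.full(n_bins, 50, dtype=int))


def lobes(chi, chi0, sigma, a1, a2, base):
    out = np.full_like(chi, base)
    for amp, c in ((a1, chi0), (a2, chi0 + 180.0)):
        for k in (-360.0, 0.0, 360.0):
            out += amp * np.exp(-0.5 * ((chi - c + k) / sigma) ** 2)
    return out


class TestAzimuthalFit:
    def test_example_lobes_161_341(self):
        prof = chi_profile(lambda c: lobes(c, 161.0, 18.0, 10.0, 8.0, 2.0))
        res = sx.fit_azimuthal(prof)
        assert res.converged and not res.isotropic
        assert res.chi0 == pytest.approx(161.0 % 180.0, abs=0.5)
        assert res.w_chi == pytest.approx(18.0, abs=0.5)

    def test_mass_wrapping_past_zero(self):
        """Lobes at 10/190 deg with 30 deg width spill across 0/360."""
        prof = chi_profile(lambda c: lobes(c, 10.0, 30.0, 12.0, 9.0, 1.0))
        res = sx.fit_azimuthal(prof)
        assert res.chi0 == pytest.approx(10.0, abs=0.5)

    @pytest.mark.parametrize("shift", [30.0, 90.0, 137.0])
    def test_wrap_around_invariance(self, shift):
        """Circularly shifting I(chi) shifts chi0 (mod 180) and keeps w_chi."""
        base = chi_profile(lambda c: lobes(c, 40.0, 22.0, 11.0, 7.0, 2.0))
        shifted = chi_profile(lambda c: lobes(c - shift, 40.0, 22.0, 11.0, 7.0, 2.0))
        r0 = sx.fit_azimuthal(base)
        r1 = sx.fit_azimuthal(shifted)
        dchi = (r1.chi0 - r0.chi0 - shift + 90.0) % 180.0 - 90.0
        assert abs(dchi) < 0.2
        assert abs(r1.w_chi - r0.w_chi) < 0.1

    def test_uniform_profile_isotropic_flag(self):
        rng = np.random.default_rng(5)
        prof = chi_profile(lambda c: 20.0 + rng.normal(0, 0.5, c.size))
        res = sx.fit_azimuthal(prof)
        assert res.isotropic

    def test_constant_profile_isotropic(self):
        prof = chi_profile(lambda c: np.full_like(c, 4.0))
        res = sx.fit_azimuthal(prof)
        assert res.isotropic and not res.converged


class TestTotalIntensity:
    def test_rectangle(self, radial_profile_factory):
        prof = radial_profile_factory(lambda q: np.ones_like(q),
                                      q_lo=0.1, q_hi=0.6, n_bins=200)
        # bin centers span slightly less than the full window
        width = prof.grid[-1] - prof.grid[0]
        assert sx.total_intensity(prof) == pytest.approx(width, rel=1e-12)

    def test_triangle(self, radial_profile_factory):
        prof = radial_profile_factory(lambda q: q - 0.1,
                                      q_lo=0.1, q_hi=0.6, n_bins=400)
        width = prof.grid[-1] - prof.grid[0]
        expected = 0.5 * width * (prof.intensity[-1] + prof.intensity[0])
        assert sx.total_intensity(prof) == pytest.approx(expected, rel=1e-6)

    def test_matches_fine_riemann_oracle(self):
        rng = np.random.default_rng(2)
        knots = rng.uniform(1.0, 5.0, 12)
        from scipy.interpolate import CubicSpline
        spline = CubicSpline(np.linspace(0.1, 0.6, 12), knots)
        coarse = np.linspace(0.1, 0.6, 250)
        prof = Profile1D("radial_q", coarse, spline(coarse),
                         np.full(coarse.size, 10, dtype=int))
        fine = np.linspace(0.1, 0.6, 200001)
        oracle = np.sum(spline(fine)) * (fine[1] - fine[0])
        assert sx.total_intensity(prof) == pytest.approx(oracle, rel=1e-3)

    def test_empty_profile_errors(self):
        prof = Profile1D("radial_q", np.linspace(0.1, 0.2, 10),
                         np.full(10, np.nan), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            sx.total_intensity(prof)


class TestOrderRatios:
    def test_equal_areas_give_unit_ratios(self, radial_profile_factory):
        D, sigma = 65.0, 0.004
        areas = {3: 2.0, 4: 2.0, 5: 2.0, 6: 2.0}

        def model(q):
            out = 30.0 * np.exp(-q * 6.0)
            for n, area in areas.items():
                out = out + gauss(q, area / (sigma * SQRT2PI),
                                  n * 2 * math.pi / D, sigma)
            return out
        prof = radial_profile_factory(model, q_lo=0.20, q_hi=0.65, n_bins=450)
        res = sx.order_ratios(prof, orders=(3, 4, 6), D_guess=65.0)
        for n in (3, 4, 6):
            assert res.ratios[n] == pytest.approx(1.0, abs=0.02)

    def test_order_consistency_centers(self, radial_profile_factory):
        """Fitted centers of all orders agree with n*2pi/D to the bin width."""
        D = 65.3
        def model(q):
            out = 20.0 * np.exp(-q * 5.0)
            for n in (3, 4, 5, 6):
                out = out + gauss(q, 15.0, n * 2 * math.pi / D, 0.004)
            return out
        prof = radial_profile_factory(model, q_lo=0.20, q_hi=0.65, n_bins=450)
        res = sx.order_ratios(prof, orders=(3, 4, 6), D_guess=65.0)
        bin_width = (0.65 - 0.20) / 450
        for n, center in res.centers.items():
            assert abs(center / n - 2 * math.pi / D) < bin_width

    def test_missing_order_flagged(self, radial_profile_factory):
        rng = np.random.default_rng(9)
        def model(q):
            out = 30.0 * np.exp(-q * 6.0) + rng.normal(0, 0.2, q.size)
            out = out + gauss(q, 40.0, 5 * 2 * math.pi / 65.0, 0.004)
            return np.maximum(out, 0)
        prof = radial_profile_factory(model, q_lo=0.20, q_hi=0.65, n_bins=450)
        res = sx.order_ratios(prof, orders=(4,), D_guess=65.0)
        assert 4 in res.flags
        assert res.ratios[4] < 0.05 or math.isnan(res.ratios[4])


def test_parameter_recovery_grid(radial_profile_factory):
    """Median |D_hat - D| < 0.02 nm over a grid of truths at SNR >= 10."""
    rng = np.random.default_rng(21)
    errors = []
    for D in (64.0, 65.0, 66.0):
        for sigma in (0.002, 0.004, 0.006):
            for snr in (10.0, 20.0, 50.0):
                center = 10 * math.pi / D
                for _ in range(4):
                    amp = 100.0
                    prof = radial_profile_factory(
                        lambda q: np.maximum(
                            gauss(q, amp, center, sigma) +
                            0.5 * amp * np.exp(-q * 4.0) +
                            rng.normal(0, amp / snr, q.size), 0.0))
                    res = sx.fit_collagen(prof)
                    if res.fit.converged:
                        errors.append(abs(res.D - D))
    assert len(errors) > 100
    assert np.median(errors) < 0.02
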