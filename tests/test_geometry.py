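"""Frame-to-profile reduction: wavevector mapping, binning, calibration."""

import numpy as np
import pytest

import saxsdic as sx
from saxsdic.geometry import _pixel_maps


class TestWavelength:
    @pytest.mark.parametrize("energy, wavelength", [
        (1.23984, 1.0),            # the conversion constant itself
        (14.0, 1.23984 / 14.0),    # beamline energy -> 0.08856 nm
        (12.398, 0.10000),
    ])
    def test_conversion(self, energy, wavelength):
        assert sx.energy_to_wavelength(energy) == pytest.approx(wavelength, abs=5e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sx.energy_to_wavelength(0.0)


class TestPixelToQ:
    def test_beam_center_is_q_zero(self, beamline_geometry):
        q, chi = sx.pixel_to_q(beamline_geometry.beam_center, beamline_geometry)
        assert q == 0.0 and chi == 0.0

    def test_hundred_pixels_from_center(self, beamline_geometry):
        # hand evaluation: 2θ = atan(0.0172 / 5.5), q = (4π/0.08856)·sin θ
        r0, c0 = beamline_geometry.beam_center
        q, _ = sx.pixel_to_q((r0, c0 + 100), beamline_geometry)
        assert q == pytest.approx(0.2219, abs=2e-4)

    def test_chi_axis_convention(self, beamline_geometry):
        r0, c0 = beamline_geometry.beam_center
        _, chi_x = sx.pixel_to_q((r0, c0 + 50), beamline_geometry)
        _, chi_y = sx.pixel_to_q((r0 + 50, c0), beamline_geometry)
        assert chi_x == pytest.approx(0.0, abs=1e-9)
        assert chi_y == pytest.approx(90.0, abs=1e-9)

    def test_round_trip_pixel(self, beamline_geometry):
        rng = np.random.default_rng(7)
        for _ in range(25):
            pixel = rng.uniform(10, 1400), rng.uniform(10, 1600)
            q, chi = sx.pixel_to_q(pixel, beamline_geometry)
            back = sx.q_chi_to_pixel(q, chi, beamline_geometry)
            assert np.hypot(back[0] - pixel[0], back[1] - pixel[1]) < 1e-6


class TestRadialIntegrate:
    def test_uniform_frame_constant_profile(self, small_geometry):
        frame = sx.DetectorFrame(np.full(small_geometry.frame_shape, 3.5))
        prof = sx.radial_integrate(frame, small_geometry, (0.1, 0.8), 50)
        populated = prof.populated
        assert populated.sum() >= 45
        assert np.allclose(prof.intensity[populated], 3.5)

    def test_sharp_ring_lands_in_its_bin(self, small_geometry):
        q_star = 0.45
        q_map = sx.pixel_q_map(small_geometry)
        counts = np.where(np.abs(q_map - q_star) < 0.004, 100.0, 1.0)
        prof = sx.radial_integrate(sx.DetectorFrame(counts), small_geometry,
                                   (0.1, 0.8), 70)
        peak_bin = prof.grid[np.nanargmax(prof.intensity)]
        assert abs(peak_bin - q_star) < (0.8 - 0.1) / 70

    def test_mass_balance(self, small_geometry):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, small_geometry.frame_shape).astype(float)
        mask = rng.random(small_geometry.frame_shape) < 0.1
        frame = sx.DetectorFrame(counts, mask)
        q_range = (0.15, 0.7)
        prof = sx.radial_integrate(frame, small_geometry, q_range, 40)
        q_map = sx.pixel_q_map(small_geometry)
        sel = (~mask) & (q_map >= q_range[0]) & (q_map < q_range[1])
        binned_total = np.nansum(prof.intensity * prof.counts_per_bin)
        assert binned_total == pytest.approx(counts[sel].sum(), rel=1e-12)

    def test_chi_sector_selects_arc(self, small_geometry):
        """A sector around an arc sees it; the opposite sector does not."""
        q_map = sx.pixel_q_map(small_geometry)
        chi_map = sx.pixel_chi_map(small_geometry)
        ring = (np.abs(q_map - 0.45) < 0.01)
        arc = ring & (np.abs((chi_map - 161.0 + 180.0) % 360.0 - 180.0) < 15.0)
        counts = np.where(arc, 50.0, 1.0)
        frame = sx.DetectorFrame(counts)
        with_arc = sx.radial_integrate(frame, small_geometry, (0.35, 0.55), 30,
                                       chi_sector=(140.0, 182.0))
        without = sx.radial_integrate(frame, small_geometry, (0.35, 0.55), 30,
                                      chi_sector=(320.0, 2.0))  # wraps through 0
        i_with = np.nanmax(with_arc.intensity)
        i_without = np.nanmax(without.intensity)
        assert i_with > 20.0
        assert i_without == pytest.approx(1.0)

    def test_zero_width_sector_rejected(self, small_geometry):
        frame = sx.DetectorFrame(np.ones(small_geometry.frame_shape))
        with pytest.raises(ValueError):
            sx.radial_integrate(frame, small_geometry, (0.1, 0.8), 40,
                                chi_sector=(45.0, 45.0))

    def test_fully_masked_errors(self, small_geometry):
        frame = sx.DetectorFrame(np.ones(small_geometry.frame_shape),
                                 np.ones(small_geometry.frame_shape, dtype=bool))
        with pytest.raises(ValueError):
            sx.radial_integrate(frame, small_geometry, (0.1, 0.8), 40)


class TestAzimuthalIntegrate:
    def _arc_frame(self, geometry, chi_centers, width=8.0, band=(0.40, 0.52)):
        q_map = sx.pixel_q_map(geometry)
        chi_map = sx.pixel_chi_map(geometry)
        counts = np.ones(geometry.frame_shape)
        in_band = (q_map >= band[0]) & (q_map < band[1])
        for c in chi_centers:
            d = np.abs((chi_map - c + 180.0) % 360.0 - 180.0)
            counts[in_band & (d < width)] += 50.0
        return sx.DetectorFrame(counts)

    def test_isotropic_ring_is_flat(self, small_geometry):
        q_map = sx.pixel_q_map(small_geometry)
        counts = np.where((q_map >= 0.4) & (q_map < 0.52), 20.0, 1.0)
        prof = sx.azimuthal_integrate(sx.DetectorFrame(counts), small_geometry,
                                      (0.40, 0.52), 36)
        vals = prof.intensity[prof.populated]
        assert vals.std() / vals.mean() < 0.02

    def test_paired_arcs_at_161_and_341(self, small_geometry):
        prof = sx.azimuthal_integrate(
            self._arc_frame(small_geometry, [161.0, 341.0]),
            small_geometry, (0.40, 0.52), 72)
        inten = np.nan_to_num(prof.intensity, nan=-1)
        first = prof.grid[np.argmax(inten)]
        away = np.abs((prof.grid - first + 180.0) % 360.0 - 180.0) > 30.0
        second = prof.grid[away][np.argmax(inten[away])]
        sep = abs(second - first)
        assert abs(sep - 180.0) <= 360.0 / 72
        assert min(abs(first - 161.0), abs(first - 341.0)) <= 5.0

    def test_rotation_shifts_profile(self, small_geometry):
        frame = self._arc_frame(small_geometry, [30.0, 210.0])
        n_bins = 72
        prof = sx.azimuthal_integrate(frame, small_geometry, (0.40, 0.52), n_bins)
        rotated = sx.DetectorFrame(np.rot90(frame.counts))
        prof_rot = sx.azimuthal_integrate(rotated, small_geometry, (0.40, 0.52), n_bins)
        # np.rot90 maps (drow, dcol) -> (-dcol, drow): chi decreases by 90 deg
        shift_bins = int(round(90.0 / (360.0 / n_bins)))
        np.testing.assert_allclose(np.roll(prof.intensity, -shift_bins),
                                   prof_rot.intensity, rtol=1e-9)

    def test_band_outside_coverage(self, small_geometry):
        frame = sx.DetectorFrame(np.ones(small_geometry.frame_shape))
        with pytest.raises(ValueError):
            sx.azimuthal_integrate(frame, small_geometry, (5.0, 6.0), 36)


class TestRefineDistance:
    def test_forward_generated_radii_recover_distance(self, beamline_geometry):
        spacings = np.array([5.838, 2.919, 1.946])  # nm, calibrant orders
        q = 2 * np.pi / spacings
        theta = np.arcsin(q * beamline_geometry.wavelength / (4 * np.pi))
        radii = beamline_geometry.distance * np.tan(2 * theta) / \
            (beamline_geometry.pixel_size * 1e-6)
        start = sx.DetectorGeometry(5.0, 172.0, beamline_geometry.beam_center,
                                    14.0, beamline_geometry.frame_shape)
        ref = sx.refine_distance(radii, spacings, start)
        assert ref.geometry.distance == pytest.approx(5.5, rel=1e-4)
        assert ref.consistent

    def test_single_ring_closed_form(self, beamline_geometry):
        q = 2 * np.pi / 5.838
        theta = np.arcsin(q * beamline_geometry.wavelength / (4 * np.pi))
        radius = 4.7 * np.tan(2 * theta) / (beamline_geometry.pixel_size * 1e-6)
        ref = sx.refine_distance([radius], [5.838], beamline_geometry)
        assert ref.geometry.distance == pytest.approx(4.7, rel=1e-10)

    def test_empty_ring_list(self, beamline_geometry):
        with pytest.raises(ValueError):
            sx.refine_distance([], [], beamline_geometry)

    def test_inconsistent_rings_flagged(self, beamline_geometry):
        with pytest.warns(UserWarning):
            ref = sx.refine_distance([500.0, 520.0], [5.838, 5.838],
                                     beamline_geometry)
        assert not ref.consistent


def test_pixel_maps_cached_and_consistent(small_geometry):
    q1, chi1 = _pixel_maps(small_geometry)
    q2, chi2 = _pixel_maps(small_geometry)
    assert q1 is q2 and chi1 is chi2
    r, c = 20, 100
    q, chi = sx.pixel_to_q((r, c), small_geometry)
    assert q1[r, c] == pytest.approx(q)
    assert chi1[r, c] == pytest.approx(chi)
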