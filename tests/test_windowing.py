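"""Spectral transforms, sideband geometry, and window-center sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from racohs import (
    Hologram,
    Spectrum,
    compute_spectrum,
    compute_window_geometry,
    default_window_size,
    extract_windowed_sideband,
    invert_spectrum,
    locate_sideband_peak,
    sample_window_centers,
)
from racohs.exceptions import (
    BoundsError,
    DimensionError,
    GeometryError,
    NoSidebandError,
    SamplingError,
    WindowSizeError,
)


class TestComputeSpectrum:
    def test_constant_image_is_pure_dc(self):
        s = compute_spectrum(np.full((16, 16), 3.0))
        assert np.isclose(abs(s.values[8, 8]), 3.0 * 256)
        off_dc = np.abs(s.values).sum() - abs(s.values[8, 8])
        assert off_dc < 1e-9

    def test_cosine_fringe_gives_two_symmetric_bins(self):
        W = 32
        x = np.arange(W)[None, :] * np.ones((16, 1))
        img = 2.0 + np.cos(2 * np.pi * 5 * x / W)
        s = compute_spectrum(img)
        mag = np.abs(s.values)
        nonzero = np.argwhere(mag > 1e-6)
        # DC plus the +-5 bins on the horizontal axis
        assert {tuple(p) for p in nonzero} == {(8, 16), (8, 16 - 5), (8, 16 + 5)}

    def test_parseval_against_direct_summation(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (24, 16))
        s = compute_spectrum(img)
        assert np.isclose(
            np.sum(np.abs(s.values) ** 2), img.size * np.sum(img**2), rtol=1e-12
        )

    def test_round_trip_reproduces_hologram(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (32, 48))
        back = invert_spectrum(compute_spectrum(img)).real
        assert np.max(np.abs(back - img)) / np.max(img) < 1e-10

    @pytest.mark.parametrize("bad", [np.ones(16), np.ones((4, 4)), np.ones((2, 64))])
    def test_degenerate_input_rejected(self, bad):
        with pytest.raises(DimensionError):
            compute_spectrum(bad)


class TestLocateSidebandPeak:
    def test_simulated_carrier_peak_verified_by_exhaustive_scan(
        self, noiseless_sphere_pair
    ):
        ref, _, _ = noiseless_sphere_pair
        s = compute_spectrum(ref)
        peak = locate_sideband_peak(s, dc_exclusion_radius=10)
        # carrier 0.1875 cycles/px on 256 -> bin +48 on the horizontal axis
        assert peak == (128, 128 + 48)
        # exhaustive oracle over the candidate half-plane
        mag = np.abs(s.values)
        best, best_val = None, -1.0
        for r in range(256):
            for c in range(129, 256):
                if (r - 128) ** 2 + (c - 128) ** 2 > 100 and mag[r, c] > best_val:
                    best, best_val = (r, c), mag[r, c]
        assert peak == best

    def test_constant_image_has_no_sideband(self):
        with pytest.raises(NoSidebandError):
            locate_sideband_peak(compute_spectrum(np.full((16, 16), 7.0)))

    def test_tie_breaks_to_first_in_row_major_order(self):
        v = np.zeros((32, 32), dtype=complex)
        v[4, 25] = 5.0
        v[20, 25] = 5.0
        assert locate_sideband_peak(Spectrum(v), 2) == (4, 25)

    def test_negative_half_plane_ignored(self):
        v = np.zeros((32, 32), dtype=complex)
        v[10, 4] = 99.0  # strong, but at negative horizontal frequency
        v[10, 28] = 1.0
        assert locate_sideband_peak(Spectrum(v), 2) == (10, 28)


class TestWindowGeometry:
    def test_reference_example_512(self):
        g = compute_window_geometry((512, 512), (256, 356))
        assert (g.a, g.b, g.c, g.d, g.Rm) == (50, 155, 256, 256, 100)

    def test_peak_near_right_edge(self):
        g = compute_window_geometry((512, 512), (256, 510))
        assert g.b == 1 and g.Rm == 2

    def test_peak_on_dc_column_rejected(self):
        with pytest.raises(GeometryError):
            compute_window_geometry((512, 512), (256, 256))

    def test_rm_is_even(self):
        for col in (300, 301, 310, 333):
            g = compute_window_geometry((512, 512), (200, col))
            assert g.Rm % 2 == 0


class TestDefaultWindowSize:
    @pytest.mark.parametrize("rm,expected", [(100, 65), (12, 7), (96, 63)])
    def test_two_thirds_snapped_odd(self, rm, expected):
        sw = default_window_size(_geom_with_rm(rm))
        assert sw == expected
        assert rm / 2 < sw < rm

    def test_too_small_rm_rejected(self):
        with pytest.raises(WindowSizeError):
            default_window_size(_geom_with_rm(6))


def _geom_with_rm(rm):
    """Geometry whose binding constraint yields exactly the requested Rm."""
    from racohs.windowing import WindowGeometry

    half = rm // 2
    return WindowGeometry(
        shape=(512, 512), peak=(256, 256 + 2 * half), a=half, b=half, c=256, d=256,
        Rm=rm,
    )


class TestSampleWindowCenters:
    def test_single_center_is_the_peak(self):
        g = _geom_with_rm(100)
        for seed in (0, 1, 99):
            plan = sample_window_centers(g, 65, 1, seed)
            assert plan.centers == (g.peak,)

    def test_eligible_square_cardinality(self):
        g = _geom_with_rm(100)
        # (Rm - SW)//2 = 17 -> 35x35 = 1225 eligible centers
        plan = sample_window_centers(g, 65, 1225, 0)
        assert len(set(plan.centers)) == 1225
        with pytest.raises(SamplingError):
            sample_window_centers(g, 65, 1226, 0)

    @pytest.mark.parametrize("bad_sw", [50, 100, 30, 101])
    def test_window_size_bound_is_hard(self, bad_sw):
        with pytest.raises(WindowSizeError):
            sample_window_centers(_geom_with_rm(100), bad_sw, 5, 0)

    def test_seeded_sampling_reproducible(self):
        g = _geom_with_rm(100)
        a = sample_window_centers(g, 65, 20, 7)
        b = sample_window_centers(g, 65, 20, 7)
        c = sample_window_centers(g, 65, 20, 8)
        assert a.centers == b.centers
        assert a.centers != c.centers

    def test_windows_fit_max_square_and_contain_peak(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rm = 2 * int(rng.integers(4, 60))
            g = _geom_with_rm(rm)
            try:
                sw = default_window_size(g)
            except WindowSizeError:
                continue
            nr = int(rng.integers(1, 21))
            try:
                plan = sample_window_centers(g, sw, nr, int(rng.integers(0, 1000)))
            except SamplingError:
                continue
            half = sw // 2
            pr, pc = g.peak
            for cr, cc in plan.centers:
                # window inside the maximum square around the peak
                assert max(abs(cr - pr), abs(cc - pc)) + half <= rm // 2
                # peak bin inside the window
                assert abs(cr - pr) <= half and abs(cc - pc) <= half

    def test_plan_round_trips_through_json_record(self):
        from racohs.windowing import WindowPlan

        plan = sample_window_centers(_geom_with_rm(100), 65, 20, 3)
        assert WindowPlan.from_dict(plan.to_dict()) == plan


class TestExtractWindowedSideband:
    def test_single_bin_translates_to_dc(self):
        v = np.zeros((32, 32), dtype=complex)
        v[10, 24] = 2.0 - 1.0j
        out = extract_windowed_sideband(Spectrum(v), (10, 24), 5)
        assert out.values[16, 16] == 2.0 - 1.0j
        assert np.count_nonzero(out.values) == 1

    def test_energy_never_increases(self, noiseless_sphere_pair):
        _, obj, _ = noiseless_sphere_pair
        s = compute_spectrum(obj)
        out = extract_windowed_sideband(s, (128, 176), 31)
        assert np.sum(np.abs(out.values) ** 2) <= np.sum(np.abs(s.values) ** 2)

    def test_recenters_carrier_to_recover_object_wave(self, rbc_optics):
        """Windowing at the peak strips the carrier: for a band-limited
        phantom the inverse transform's phase matches the simulator's
        ground-truth object phase pixel for pixel."""
        from racohs import SimulationConfig, simulate_hologram_pair, wrap_phase
        from racohs.phase import HeightMap
        from racohs.simulate import Phantom

        yy, xx = np.mgrid[0:128, 0:128]
        bump = 3.0 * np.exp(-((xx - 63.5) ** 2 + (yy - 63.5) ** 2) / (2 * 12.0**2))
        phantom = Phantom(height=HeightMap(values=bump, pixel_pitch=0.055))
        cfg = SimulationConfig(
            optics=rbc_optics, noise_sigma=0.0, beam_envelope_sigma=None,
            grid=(128, 128), seed=0,
        )
        _, obj = simulate_hologram_pair(phantom, cfg)
        s = compute_spectrum(obj)
        peak = locate_sideband_peak(s)
        g = compute_window_geometry(s.shape, peak)
        field = invert_spectrum(extract_windowed_sideband(s, peak, default_window_size(g)))
        truth_phi = rbc_optics.wavenumber * rbc_optics.delta_n * bump
        err = wrap_phase(np.angle(field) - truth_phi)
        assert np.abs(err - np.median(err)).max() < 0.05

    def test_window_overrun_rejected(self):
        s = Spectrum(np.ones((32, 32), dtype=complex))
        with pytest.raises(BoundsError):
            extract_windowed_sideband(s, (2, 16), 7)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_center_sampling_is_deterministic_per_seed(seed):
    g = _geom_with_rm(40)
    p1 = sample_window_centers(g, 27, 10, seed)
    p2 = sample_window_centers(g, 27, 10, seed)
    assert p1.centers == p2.centers and p1.centers[0] == g.peak
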