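"""Fringe demodulation and the phase → index → density → pressure chain."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from paw.errors import (
    BoundsError,
    IncompatibleFieldsError,
    NoCarrierError,
    UnboundedPeakError,
    UnphysicalDensityError,
)
from paw.fields import Rect, ScalarField
from paw.interferometry import (
    InterferogramPair,
    PressureProfile,
    TaitEOS,
    density_to_pressure,
    detect_carrier,
    extract_phase,
    index_to_density,
    phase_difference,
    phase_to_index,
    pressure_map,
    pressure_profile,
    profile_fwhm,
    remove_plane,
)
from paw.synthetic import (
    GeometryConfig,
    PulseConfig,
    SimulationConfig,
    make_pressure_field,
    render_interferogram,
)


def fringes(shape=(128, 128), carrier=0.125, visibility=0.8, mean=100.0,
            phase=0.0):
    cols = np.arange(shape[1])[None, :]
    grid = mean * (1 + visibility * np.cos(2 * np.pi * carrier * cols + phase))
    return ScalarField(np.broadcast_to(grid, shape).copy() if np.isscalar(phase)
                       else grid, "intensity", 1.0)


class TestExtractPhase:
    def test_pure_carrier_gives_flat_phase(self):
        img = fringes()
        phase = remove_plane(extract_phase(img))
        assert np.abs(phase.grid).max() < 1e-6

    def test_gaussian_bump_recovered(self):
        shape = (256, 256)
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        bump = 4.6 * np.exp(-((rows - 128) ** 2 + (cols - 128) ** 2) / (2 * 30**2))
        img = fringes(shape, carrier=0.25, phase=bump)
        ref = fringes(shape, carrier=0.25, phase=np.zeros(shape))
        dphi = phase_difference(extract_phase(img), extract_phase(ref))
        assert dphi.grid.max() == pytest.approx(4.6, rel=0.02)

    def test_no_carrier_raises(self):
        rng = np.random.default_rng(0)
        noise = ScalarField(100 + rng.normal(0, 1, (64, 64)), "intensity", 1.0)
        with pytest.raises(NoCarrierError):
            extract_phase(noise)

    def test_invariant_under_intensity_scaling(self):
        shape = (128, 128)
        cols = np.mgrid[0:shape[0], 0:shape[1]][1]
        bump = 2.0 * np.exp(-((cols - 64) ** 2) / (2 * 15**2))
        img = fringes(shape, phase=bump)
        p1 = extract_phase(img)
        p2 = extract_phase(img.with_grid(3.7 * img.grid))
        assert np.abs(p1.grid - p2.grid).max() < 1e-6

    def test_detect_carrier_frequency(self):
        img = fringes(carrier=0.125)
        fr, fc = detect_carrier(img)
        assert fr == pytest.approx(0.0, abs=1e-9)
        assert fc == pytest.approx(0.125, abs=1e-9)


class TestPhaseDifference:
    def test_identical_inputs_zero(self):
        p = extract_phase(fringes())
        d = phase_difference(p, p)
        assert np.abs(d.grid).max() < 1e-9

    def test_additive_bump(self):
        base = ScalarField(np.zeros((64, 64)), "phase_rad", 1.0)
        cols = np.mgrid[0:64, 0:64][1]
        bump = 1.5 * np.exp(-((cols - 20) ** 2) / (2 * 5**2))
        d = phase_difference(base.with_grid(bump), base)
        assert d.grid.max() == pytest.approx(1.5, abs=1e-3)

    def test_tilt_removed(self):
        rows, cols = np.mgrid[0:64, 0:64]
        bump = 2.0 * np.exp(-((rows - 32) ** 2 + (cols - 20) ** 2) / (2 * 4**2))
        tilt = 0.01 * rows - 0.02 * cols + 0.3
        base = ScalarField(np.zeros((64, 64)), "phase_rad", 1.0)
        d = phase_difference(base.with_grid(bump + tilt), base)
        # quiet margin (right 10%) carries only the tilt, which must vanish
        assert np.abs(d.grid - bump).max() < 1e-3

    def test_shape_mismatch(self):
        a = ScalarField(np.zeros((64, 64)), "phase_rad", 1.0)
        b = ScalarField(np.zeros((32, 64)), "phase_rad", 1.0)
        with pytest.raises(IncompatibleFieldsError):
            phase_difference(a, b)


class TestConversionChain:
    def test_phase_to_index_value(self):
        dphi = ScalarField(np.full((8, 8), 2 * np.pi), "phase_rad", 1.0)
        dn = phase_to_index(dphi, wavelength_nm=400, path_mm=2)
        assert dn.grid == pytest.approx(2.0e-4)

    def test_phase_to_index_inverse_path(self):
        dphi = ScalarField(np.full((8, 8), 1.0), "phase_rad", 1.0)
        a = phase_to_index(dphi, 400, 2.0).grid
        b = phase_to_index(dphi, 400, 1.0).grid
        assert b == pytest.approx(2 * a)

    def test_index_to_density_value(self):
        dn = ScalarField(np.full((8, 8), 3.22e-4), "delta_n", 1.0)
        assert index_to_density(dn).grid == pytest.approx(1.0e-3)

    def test_index_to_density_linear(self):
        a = ScalarField(np.random.default_rng(1).normal(0, 1e-4, (8, 8)), "delta_n", 1.0)
        b = ScalarField(np.random.default_rng(2).normal(0, 1e-4, (8, 8)), "delta_n", 1.0)
        lhs = index_to_density(a.with_grid(a.grid + b.grid)).grid
        rhs = index_to_density(a).grid + index_to_density(b).grid
        assert lhs == pytest.approx(rhs)


class TestTaitEOS:
    def test_equilibrium(self):
        eos = TaitEOS.water()
        drho = ScalarField(np.zeros((8, 8)), "delta_rho_gcm3", 1.0)
        assert density_to_pressure(drho, eos).grid == pytest.approx(0.0)

    def test_one_mpa_density_change(self):
        # small-signal oracle: P ~ cs^2 * drho -> 1 MPa needs 4.55e-4 g/cm3
        eos = TaitEOS.water()
        drho = ScalarField(np.full((8, 8), 4.55e-4), "delta_rho_gcm3", 1.0)
        p = density_to_pressure(drho, eos).grid
        assert p == pytest.approx(1.0, rel=0.01)

    def test_acoustic_limit(self):
        eos = TaitEOS.water()
        for drho_val in (1e-4, 5e-4, 9e-4):
            field = ScalarField(np.full((8, 8), drho_val), "delta_rho_gcm3", 1.0)
            exact = density_to_pressure(field, eos).grid[0, 0]
            linear = eos.k0_Pa * drho_val / eos.rho0_gcm3 * 1e-6
            assert exact == pytest.approx(linear, rel=0.01)

    def test_monotone_in_density(self):
        eos = TaitEOS.water()
        drho = np.linspace(-5e-3, 5e-3, 64)
        p = eos.pressure_gauge_MPa(drho)
        assert np.all(np.diff(p) > 0)

    def test_inversion_round_trip(self):
        eos = TaitEOS.water()
        p = np.linspace(-3, 3, 31)
        assert eos.pressure_gauge_MPa(eos.density_change_gcm3(p)) == pytest.approx(p)

    def test_unphysical_density(self):
        eos = TaitEOS.water()
        drho = ScalarField(np.full((8, 8), -1.0), "delta_rho_gcm3", 1.0)
        with pytest.raises(UnphysicalDensityError):
            density_to_pressure(drho, eos)


class TestPressureMap:
    def test_identical_pair_zero_map(self):
        img = fringes()
        pair = InterferogramPair(img, img, 400, 2)
        pmap = pressure_map(pair, TaitEOS.water())
        assert np.abs(pmap.grid).max() < 1e-6

    def test_round_trip_noise_free(self, default_cfg):
        field = make_pressure_field(default_cfg)
        pair = render_interferogram(field, default_cfg)
        pmap = pressure_map(pair, default_cfg.eos)
        err = np.abs(pmap.grid - field.grid).max() / field.grid.max()
        assert err < 0.05

    def test_two_pulses_located(self):
        cfg = SimulationConfig(seed=0, geometry=GeometryConfig((384, 384), 1.0))
        x = np.arange(384) * 1.0
        lobe = lambda c: np.where(np.abs(x - c) < 36,
                                  0.5 * (1 + np.cos(np.pi * (x - c) / 36)), 0.0)
        profile = 0.8 * lobe(120.0) + 0.8 * lobe(240.0)
        field = ScalarField(np.broadcast_to(profile, (384, 384)).copy(),
                            "pressure_MPa", 1.0)
        pmap = pressure_map(render_interferogram(field, cfg), cfg.eos)
        prof = pressure_profile(pmap, axis="cols")
        peaks, _ = find_peaks(prof.mean_MPa, height=0.4)
        assert len(peaks) == 2
        assert abs(prof.positions_um[peaks[0]] - 120.0) <= 1.0
        assert abs(prof.positions_um[peaks[1]] - 240.0) <= 1.0


class TestPressureProfile:
    def test_constant_map(self):
        pmap = ScalarField(np.full((32, 32), 2.0), "pressure_MPa", 1.0)
        prof = pressure_profile(pmap, axis="cols")
        assert prof.mean_MPa == pytest.approx(2.0)
        assert prof.std_MPa == pytest.approx(0.0)

    def test_noise_raises_std(self):
        rng = np.random.default_rng(5)
        sigma = 0.3
        ridge = np.broadcast_to(np.linspace(0, 1, 64), (256, 64)).copy()
        noisy = ridge + rng.normal(0, sigma, ridge.shape)
        prof_clean = pressure_profile(ScalarField(ridge, "pressure_MPa", 1.0))
        prof_noisy = pressure_profile(ScalarField(noisy, "pressure_MPa", 1.0))
        assert prof_clean.std_MPa.max() < 1e-12
        # sample std across 256 rows approaches sigma
        assert prof_noisy.std_MPa.mean() == pytest.approx(sigma, rel=0.1)

    def test_roi_bounds(self):
        pmap = ScalarField(np.zeros((32, 32)), "pressure_MPa", 1.0)
        with pytest.raises(BoundsError):
            pressure_profile(pmap, roi=Rect(0, 40, 0, 10))

    def test_gaussian_ridge_profile(self):
        x = np.arange(128)
        ridge = 1.5 * np.exp(-((x - 64) ** 2) / (2 * 10**2))
        pmap = ScalarField(np.broadcast_to(ridge, (64, 128)).copy(),
                           "pressure_MPa", 2.0)
        prof = pressure_profile(pmap, axis="cols")
        assert prof.mean_MPa.max() == pytest.approx(1.5)
        assert prof.positions_um[np.argmax(prof.mean_MPa)] == pytest.approx(128.0)


class TestProfileFWHM:
    def test_gaussian_closed_form(self):
        x = np.linspace(0, 200, 2001)  # 0.1 um sampling: dense-grid oracle
        sigma = 15.3
        prof = PressureProfile(x, np.exp(-((x - 100) ** 2) / (2 * sigma**2)), np.zeros_like(x))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma  # 36.03 um
        assert profile_fwhm(prof) == pytest.approx(expected, abs=0.01)

    def test_gaussian_coarse_sampling(self):
        x = np.arange(0, 200, 2.0)  # 2 um pixels
        sigma = 15.3
        prof = PressureProfile(x, np.exp(-((x - 100) ** 2) / (2 * sigma**2)), np.zeros_like(x))
        assert profile_fwhm(prof) == pytest.approx(36.03, abs=0.5)

    def test_triangle_half_width(self):
        x = np.linspace(0, 100, 1001)
        w = 20.0
        y = np.clip(1 - np.abs(x - 50) / w, 0, None)
        prof = PressureProfile(x, y, np.zeros_like(x))
        assert profile_fwhm(prof) == pytest.approx(w, abs=0.01)

    def test_unbounded_peak(self):
        x = np.linspace(0, 10, 11)
        prof = PressureProfile(x, np.linspace(0.6, 1.0, 11), np.zeros_like(x))
        with pytest.raises(UnboundedPeakError):
            profile_fwhm(prof)
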