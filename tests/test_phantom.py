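"""Forward model: fluence, escape kernel, emission lines, frame rendering."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

import orchid
from orchid.phantom import (
    DEFAULT_OPTICS,
    CCDFrame,
    DetectorModel,
    EmitterVolume,
    Layer,
    OpticalProperties,
    Phantom,
    ReferenceSpectrum,
    ScanPlan,
    SpectralLine,
    boundary_mismatch_A,
    builtin_fixtures,
    emission_wavelength_profile,
    excitation_fluence,
    render_frame,
    simulate_scan,
    surface_escape_kernel,
    uniform_background_phantom,
)


def single_emitter_phantom(depth_top, depth_bottom, concentration=1e7, thickness=12.0):
    """One small QD-like emitter column in a uniform gel slab."""
    spec = ReferenceSpectrum("QD900", "direct_wavelength", (SpectralLine(900.0, 30.0, 1.0),))
    return Phantom(
        layers=(Layer(thickness, DEFAULT_OPTICS),),
        emitters=(
            EmitterVolume((9.0, 11.0, 9.0, 11.0, depth_top, depth_bottom), "QD900", concentration),
        ),
        spectra=(spec,),
        lateral_extent=(20.0, 20.0),
    )


class TestTypes:
    def test_optics_invariants(self):
        with pytest.raises(ValueError):
            OpticalProperties(-0.1, 1.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.1, 0.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.1, 1.0, n=0.9)

    def test_mu_eff_formula(self):
        o = OpticalProperties(0.01, 1.0)
        assert o.mu_eff == pytest.approx(math.sqrt(3 * 0.01 * 1.01))

    def test_emitter_region_must_fit(self):
        with pytest.raises(ValueError, match="outside"):
            single_emitter_phantom(10.0, 14.0)  # deeper than the 12 mm slab

    def test_unknown_spectrum_reference(self):
        with pytest.raises(ValueError, match="unknown spectrum"):
            Phantom(
                layers=(Layer(5.0),),
                emitters=(EmitterVolume((0, 1, 0, 1, 0, 1), "nope", 1.0),),
                spectra=(),
                lateral_extent=(10.0, 10.0),
            )

    def test_plan_invariants(self):
        with pytest.raises(ValueError):
            ScanPlan((0.0,), (0.0,), 830.0, 800.0, 1.0)
        with pytest.raises(ValueError):
            ScanPlan((0.0,), (0.0,), 800.0, 830.0, -1.0)
        plan = ScanPlan.from_grid(0, 0, 3, 2, 1.0, lambda_start=800, lambda_stop=802, lambda_step=1)
        assert plan.n_positions == 6
        assert len(plan.lambda_axis) == 3


class TestExcitationFluence:
    def test_surface_normalisation(self):
        ph = uniform_background_phantom()
        assert excitation_fluence(ph, 0.0, 785.0) == 1.0

    def test_hand_arithmetic_single_layer(self):
        ph = uniform_background_phantom()
        expected = math.exp(-math.sqrt(3 * 0.01 * 1.01) * 1.0)
        assert excitation_fluence(ph, 1.0, 785.0) == pytest.approx(expected, rel=1e-12)

    def test_piecewise_additivity(self):
        one = Phantom((Layer(6.0),), (), (), (10.0, 10.0))
        two = Phantom((Layer(2.5), Layer(3.5)), (), (), (10.0, 10.0))
        for z in (0.0, 1.0, 2.5, 3.0, 6.0):
            assert excitation_fluence(one, z, 785.0) == pytest.approx(
                excitation_fluence(two, z, 785.0), rel=1e-12
            )

    def test_depth_outside_phantom(self):
        ph = uniform_background_phantom(thickness=5.0)
        with pytest.raises(ValueError):
            excitation_fluence(ph, 6.0, 785.0)
        with pytest.raises(ValueError):
            excitation_fluence(ph, -0.1, 785.0)


class TestEscapeKernel:
    def escape_fraction(self, z, optics, A=1.0):
        val, _ = quad(
            lambda r: float(surface_escape_kernel(z, optics, r, A=A)) * 2 * math.pi * r,
            0, 400, limit=300,
        )
        return val

    @pytest.mark.parametrize("z", [0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
    def test_escape_fraction_is_probability(self, z):
        frac = self.escape_fraction(z, DEFAULT_OPTICS)
        assert 0.0 < frac <= 1.0

    def test_escape_fraction_other_optics(self):
        optics = OpticalProperties(0.05, 2.0)
        for z in (0.5, 3.0):
            assert 0.0 < self.escape_fraction(z, optics) <= 1.0

    def test_radial_second_moment_grows_with_depth(self):
        def m2(z):
            num, _ = quad(
                lambda r: float(surface_escape_kernel(z, DEFAULT_OPTICS, r)) * 2 * math.pi * r**3,
                0, 600, limit=400,
            )
            den, _ = quad(
                lambda r: float(surface_escape_kernel(z, DEFAULT_OPTICS, r)) * 2 * math.pi * r,
                0, 600, limit=400,
            )
            return num / den

        zs = np.array([0.5, 1.0, 2.0, 4.0, 7.0, 10.0])
        moments = [m2(z) for z in zs]
        assert np.all(np.diff(moments) > 0)

    def test_peak_at_zero_offset(self):
        for z in (0.5, 2.0, 8.0):
            k = surface_escape_kernel(z, DEFAULT_OPTICS, np.array([0.0, 0.3, 1.0, 3.0]))
            assert np.all(np.diff(k) < 0)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            surface_escape_kernel(0.0, DEFAULT_OPTICS, 1.0)

    def test_boundary_factor(self):
        assert boundary_mismatch_A(1.0) == pytest.approx(1.0, abs=0.01)
        assert boundary_mismatch_A(1.4) > 1.5


class TestEmissionProfile:
    def test_direct_line_peaks_at_center(self):
        spec = ReferenceSpectrum("QD900", "direct_wavelength", (SpectralLine(900.0, 30.0, 1.0),))
        lam = np.arange(850.0, 950.5, 0.5)
        prof = emission_wavelength_profile(spec, 785.0, lam)
        assert lam[np.argmax(prof)] == pytest.approx(900.0, abs=0.25)

    def test_zero_amplitude_gives_zero_vector(self):
        spec = ReferenceSpectrum("null", "direct_wavelength", (SpectralLine(900.0, 10.0, 0.0),))
        prof = emission_wavelength_profile(spec, 785.0, np.arange(880.0, 920.0))
        assert not prof.any()

    def test_raman_line_converts_to_wavelength(self):
        spec = ReferenceSpectrum("dttc", "raman_shift", (SpectralLine(497.0, 2.0, 1.0),))
        lam = np.arange(810.0, 825.0, 0.1)
        prof = emission_wavelength_profile(spec, 785.0, lam)
        # independent arithmetic: 1e7/785 - 497 cm^-1 -> back to nm
        expected = 1e7 / (1e7 / 785.0 - 497.0)
        assert lam[np.argmax(prof)] == pytest.approx(expected, abs=0.06)

    def test_unknown_mode_rejected_at_construction(self):
        with pytest.raises(ValueError, match="mode"):
            ReferenceSpectrum("x", "wavenumber", (SpectralLine(900.0, 1.0, 1.0),))

    def test_axis_must_increase(self):
        spec = ReferenceSpectrum("QD900", "direct_wavelength", (SpectralLine(900.0, 30.0, 1.0),))
        with pytest.raises(ValueError):
            emission_wavelength_profile(spec, 785.0, np.array([900.0, 899.0]))


class TestRenderFrame:
    def test_empty_phantom_is_flat_dark(self, small_detector):
        ph = Phantom((Layer(10.0),), (), (), (20.0, 20.0))
        fr = render_frame(ph, small_detector, (10, 10), 850.0, 1.0, 785.0, noise="off")
        assert np.all(fr.data == small_detector.dark_offset)

    def test_exposure_linearity_exact(self, small_detector):
        ph = single_emitter_phantom(1.0, 2.0)
        f1 = render_frame(ph, small_detector, (10, 10), 900.0, 1.0, 785.0, noise="off")
        f2 = render_frame(ph, small_detector, (10, 10), 900.0, 2.0, 785.0, noise="off")
        np.testing.assert_allclose(
            f2.data - small_detector.dark_offset,
            2.0 * (f1.data - small_detector.dark_offset),
            rtol=1e-12, atol=1e-10 * small_detector.dark_offset,
        )

    def test_concentration_and_gain_linearity(self, small_detector):
        ph1 = single_emitter_phantom(1.0, 2.0, concentration=1e7)
        ph3 = single_emitter_phantom(1.0, 2.0, concentration=3e7)
        f1 = render_frame(ph1, small_detector, (10, 10), 900.0, 1.0, 785.0, noise="off")
        f3 = render_frame(ph3, small_detector, (10, 10), 900.0, 1.0, 785.0, noise="off")
        np.testing.assert_allclose(
            f3.data - small_detector.dark_offset,
            3.0 * (f1.data - small_detector.dark_offset),
            rtol=1e-12,
        )
        det2 = replace(small_detector, gain=2.0)
        f2 = render_frame(ph1, det2, (10, 10), 900.0, 1.0, 785.0, noise="off")
        np.testing.assert_allclose(
            f2.data - det2.dark_offset,
            2.0 * (f1.data - small_detector.dark_offset),
            rtol=1e-12,
        )

    def test_deeper_emitter_spreads_wider(self, small_detector):
        """The offset method's premise: depth maps to radial broadening."""
        wide = replace(small_detector, magnification=0.5)  # 48 um sample pixels
        moments = []
        for z in (0.5, 2.0):
            ph = single_emitter_phantom(z, z + 0.5)
            fr = render_frame(ph, wide, (10, 10), 900.0, 1.0, 785.0, noise="off")
            img = fr.data - wide.dark_offset
            iy, ix = np.indices(img.shape)
            r2 = (iy - 64) ** 2 + (ix - 64) ** 2
            moments.append((img * r2).sum() / img.sum())
        assert moments[1] > 1.5 * moments[0]

    def test_stage_off_phantom_rejected(self, small_detector):
        ph = single_emitter_phantom(1.0, 2.0)
        with pytest.raises(ValueError, match="off the phantom"):
            render_frame(ph, small_detector, (25.0, 10.0), 900.0, 1.0, 785.0)

    def test_noise_reproducible_under_seed(self, tiny_detector):
        ph = uniform_background_phantom(extent=(20.0, 20.0))
        a = render_frame(ph, tiny_detector, (10, 10), 850.0, 1.0, 785.0, noise="on", seed=7)
        b = render_frame(ph, tiny_detector, (10, 10), 850.0, 1.0, 785.0, noise="on", seed=7)
        c = render_frame(ph, tiny_detector, (10, 10), 850.0, 1.0, 785.0, noise="on", seed=8)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_poisson_shot_noise_variance(self, tiny_detector):
        """Sample variance of a constant-expectation pixel ~ gain * signal."""
        ph = uniform_background_phantom(extent=(20.0, 20.0))
        expect = render_frame(ph, tiny_detector, (10, 10), 850.0, 1.0, 785.0, noise="off")
        signal = expect.data - tiny_detector.dark_offset
        rng = np.random.default_rng(123)
        stack = np.stack(
            [
                render_frame(
                    ph, tiny_detector, (10, 10), 850.0, 1.0, 785.0, noise="on", rng=rng
                ).data
                for _ in range(1000)
            ]
        )
        var = stack.var(axis=0)
        ratio = var / (tiny_detector.gain * signal)
        assert abs(np.median(ratio) - 1.0) < 0.1


class TestSimulateScan:
    def test_frame_count_and_grid(self, tiny_detector):
        ph = uniform_background_phantom(extent=(20.0, 20.0))
        plan = ScanPlan.from_grid(5, 5, 3, 3, 2.0, lambda_start=800, lambda_stop=802, lambda_step=1)
        acq = simulate_scan(ph, tiny_detector, plan, noise="off", seed=0)
        assert acq.frames.shape == (9, 3, 16, 16)

    def test_identical_seeds_identical_stacks(self, tiny_detector):
        ph = uniform_background_phantom(extent=(20.0, 20.0))
        plan = ScanPlan.from_grid(5, 5, 2, 2, 4.0, lambda_start=800, lambda_stop=801, lambda_step=1)
        a = simulate_scan(ph, tiny_detector, plan, noise="on", seed=11)
        b = simulate_scan(ph, tiny_detector, plan, noise="on", seed=11)
        c = simulate_scan(ph, tiny_detector, plan, noise="on", seed=12)
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_noise_off_matches_between_seeds(self, tiny_detector):
        ph = uniform_background_phantom(extent=(20.0, 20.0))
        plan = ScanPlan.from_grid(5, 5, 2, 1, 4.0, lambda_start=800, lambda_stop=801, lambda_step=1)
        a = simulate_scan(ph, tiny_detector, plan, noise="off", seed=1)
        b = simulate_scan(ph, tiny_detector, plan, noise="off", seed=999)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_error_carries_position_context(self, tiny_detector):
        ph = single_emitter_phantom(1.0, 2.0)
        plan = ScanPlan.from_grid(18.0, 10.0, 2, 1, 4.0,
                                  lambda_start=898, lambda_stop=902, lambda_step=2)
        with pytest.raises(ValueError, match="position"):
            simulate_scan(ph, tiny_detector, plan, noise="off", seed=0)

    def test_negative_autofluorescence_rejected(self, tiny_detector):
        bad = Phantom(
            (Layer(5.0, DEFAULT_OPTICS, (-10.0,)),), (), (), (20.0, 20.0)
        )
        plan = ScanPlan.from_grid(10, 10, 1, 1, 1.0, lambda_start=800, lambda_stop=801, lambda_step=1)
        with pytest.raises(ValueError, match="autofluorescence"):
            simulate_scan(bad, tiny_detector, plan, noise="off", seed=0)


class TestFixtures:
    def test_stacked_dual_3mm_geometry(self):
        ph, plan = builtin_fixtures("stacked_dual_3mm")
        assert [l.thickness for l in ph.layers] == [3.0, 3.0]
        top = next(e for e in ph.emitters if e.region[4] == 0.0)
        bottom = next(e for e in ph.emitters if e.region[4] == 3.0)
        assert top.spectrum_id == "GNS-DTTC"
        assert bottom.spectrum_id == "GNS-IR780"
        assert plan.lambda_axis[0] == 800.0 and plan.lambda_axis[-1] == 880.0

    def test_nano_qd_grid_and_depth(self):
        ph, plan = builtin_fixtures("nano_qd")
        # 4 cm x 4 cm at 4 mm increments -> 11 x 11 stage positions
        assert len(plan.x_positions) == 11 and len(plan.y_positions) == 11
        assert plan.x_positions[-1] - plan.x_positions[0] == pytest.approx(40.0)
        assert plan.exposure == pytest.approx(0.1)
        assert all(e.spectrum_id == "QD900" for e in ph.emitters)
        assert all(e.region[4] == 1.0 for e in ph.emitters)
        qd = ph.spectrum("QD900")
        assert qd.lines[0].center == 900.0

    def test_single_layer_cube_geometry(self):
        ph, plan = builtin_fixtures("single_layer_cube")
        cube = ph.emitters[0]
        x0, x1, y0, y1, z0, z1 = cube.region
        assert (x1 - x0, y1 - y0) == (5.0, 5.0)
        assert z0 == 5.0  # below a 5 mm top slab
        assert ph.layers[0].thickness == 5.0 and ph.layers[-1].thickness == 5.0

    def test_embedded_dual_layer_order(self):
        # deeper dye is GNS-DTTC in the embedded 2 mm configuration
        ph, _ = builtin_fixtures("embedded_dual_2mm")
        by_depth = sorted(ph.emitters, key=lambda e: e.region[4])
        assert by_depth[0].spectrum_id == "GNS-IR780"
        assert by_depth[1].spectrum_id == "GNS-DTTC"

    def test_unknown_fixture(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            builtin_fixtures("mystery")
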