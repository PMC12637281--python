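import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_resonance_fields
from spinpol import spinsim
from spinpol.constants import MU_B_MHZ_PER_MT
from spinpol.exceptions import TruncationWarning, ValidationError
from spinpol.spinsim import (
    LineBroadening,
    NucleusCoupling,
    OrientationDistribution,
    SpinSystem,
    TensorSpec,
    _stick_histogram,
    _system_resonances,
    compose_components,
    frequency_rescale,
    golden_spiral_grid,
    order_weight,
    resonance_lines,
    simulate_cw_spectrum,
    spectral_density,
)

MAGIC = np.arccos(1.0 / np.sqrt(3.0))


class TestOrderWeight:
    def test_isotropic_is_unity(self):
        alphas = np.linspace(0, np.pi, 17)
        assert np.allclose(order_weight(alphas, 0.0), 1.0)

    @pytest.mark.parametrize("lam", [-5.0, -1.0, 0.0, 0.3, 1.0, 5.0])
    def test_magic_angle_unity(self, lam):
        assert order_weight(MAGIC, lam) == pytest.approx(1.0, abs=1e-12)

    def test_pole_value(self):
        assert order_weight(0.0, 2.0) == pytest.approx(np.exp(-2.0), rel=1e-12)

    @given(
        st.floats(0, np.pi, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_positive(self, alpha, lam):
        assert order_weight(alpha, lam) > 0

    def test_large_lambda_concentrates_at_equator(self, grid_medium):
        mean_alpha = []
        for lam in (0.0, 1.0, 3.0, 8.0):
            w = grid_medium.weights * order_weight(grid_medium.theta, lam)
            mean_alpha.append(np.sum(w * grid_medium.theta) / w.sum())
        assert np.all(np.diff(mean_alpha) > 0)  # toward alpha = pi/2


class TestResonanceLines:
    def test_free_electron_closed_form(self):
        system = SpinSystem(TensorSpec([2.0023] * 3))
        lines = resonance_lines(system, (0.4, 1.1), 9.6)
        expected = 9600.0 / (MU_B_MHZ_PER_MT * 2.0023)
        assert len(lines) == 1
        assert lines[0][0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(342.55, abs=0.01)

    def test_isotropic_doublet_splitting(self):
        system = SpinSystem(
            TensorSpec([2.0023] * 3),
            [NucleusCoupling("13C", 0.5, TensorSpec([64.69] * 3))],
        )
        lines = resonance_lines(system, (0.7, 0.2), 9.6)
        strong = [b for b, amp in lines if amp > 0.1]
        expected_split = 64.69 / (MU_B_MHZ_PER_MT * 2.0023)
        assert len(strong) == 2
        assert strong[1] - strong[0] == pytest.approx(expected_split, rel=5e-3)

    def test_nonphysical_spin_rejected(self):
        with pytest.raises(ValidationError):
            NucleusCoupling("13C", 0.3, TensorSpec([1, 1, 1]))

    @pytest.mark.parametrize(
        "theta,phi",
        [(0.0, 0.0), (0.3, 0.9), (0.8, 2.2), (1.2, 4.0), (np.pi / 2, 0.5)],
    )
    def test_sar1_matches_full_diagonalization_oracle(self, sar1, theta, phi):
        lines = resonance_lines(sar1, (theta, phi), 9.6)
        oracle = oracle_resonance_fields(sar1, theta, phi, 9.6)
        strong = sorted(b for b, a in lines if a > 0.01)
        oracle_strong = sorted(b for b, a in oracle if a > 0.01)
        assert len(strong) == len(oracle_strong)
        assert np.max(np.abs(np.array(strong) - np.array(oracle_strong))) < 0.01

    def test_two_nuclei_additive_model_near_oracle(self):
        """Pairwise-exact lines stay within 0.02 mT of the full product
        Hamiltonian when a proton joins the 13C coupling."""
        system = SpinSystem(
            TensorSpec([2.0035] * 3),
            [
                NucleusCoupling("13C", 0.5, TensorSpec([-2.0, -16.0, 65.0], [1.5, 1.3, 0.76])),
                NucleusCoupling("1H", 0.5, TensorSpec([20.0, 25.0, 55.0], [0.2, 0.9, 0.1])),
            ],
        )
        for theta, phi in [(0.4, 0.7), (1.1, 3.0)]:
            lines = resonance_lines(system, (theta, phi), 9.6)
            oracle = oracle_resonance_fields(system, theta, phi, 9.6)
            strong = sorted(b for b, a in lines if a > 0.02)
            oracle_strong = sorted(b for b, a in oracle if a > 0.02)
            assert len(strong) == len(oracle_strong)
            assert np.max(np.abs(np.array(strong) - np.array(oracle_strong))) < 0.02


class TestSimulateCwSpectrum:
    def test_derivative_integrates_to_zero(self, sar1, isotropic_powder, grid_small):
        spec = simulate_cw_spectrum(sar1, isotropic_powder, grid_small, (325, 360, 2048), 9.6)
        total = abs(np.trapezoid(spec.intensity, spec.field_mT))
        scale = np.trapezoid(np.abs(spec.intensity), spec.field_mT)
        assert total < 1e-3 * scale

    def test_single_isotropic_line_antisymmetric(self, isotropic_powder, grid_small):
        system = SpinSystem(TensorSpec([2.0023] * 3), line_broadening=LineBroadening(
            shape="gaussian", fwhm_mT=0.5))
        spec = simulate_cw_spectrum(
            system, isotropic_powder, grid_small, (337.55, 347.55, 2001), 9.6
        )
        center = 9600.0 / (MU_B_MHZ_PER_MT * 2.0023)
        rel = spec.field_mT - center
        mirrored = np.interp(-rel, rel, spec.intensity)
        assert np.max(np.abs(spec.intensity + mirrored)) < 2e-3 * np.max(np.abs(spec.intensity))

    def test_axial_powder_matches_monte_carlo_histogram(self):
        """Stick histogram of an axial-g powder vs 1e6 random orientations."""
        system = SpinSystem(TensorSpec([2.010, 2.010, 2.002]))
        grid = golden_spiral_grid(20000)
        axis = np.linspace(339.0, 343.5, 300)
        fields, intens = _system_resonances(system, grid.n_vecs, 9.6)
        hist, _ = _stick_histogram(axis, fields, intens * grid.weights[:, None])
        rng = np.random.default_rng(7)
        cos_t = rng.uniform(0, 1, 1_000_000)
        gmat = system.g.matrix()
        phi = rng.uniform(0, 2 * np.pi, cos_t.size)
        st_ = np.sqrt(1 - cos_t**2)
        n = np.stack([st_ * np.cos(phi), st_ * np.sin(phi), cos_t], axis=1)
        geff = np.linalg.norm(n @ gmat, axis=1)
        b_mc = 9600.0 / (MU_B_MHZ_PER_MT * geff)
        mc_hist, _ = _stick_histogram(axis, b_mc, np.full(b_mc.size, 1.0 / b_mc.size))
        hist /= hist.sum()
        mc_hist /= mc_hist.sum()
        assert np.abs(hist - mc_hist).sum() < 0.01

    def test_hyperfine_broadens_spectrum(self, sar1, isotropic_powder, grid_small):
        uncoupled = SpinSystem(sar1.g, [], sar1.line_broadening)
        frange = (325, 360, 2048)
        with_c = simulate_cw_spectrum(sar1, isotropic_powder, grid_small, frange, 9.6)
        without = simulate_cw_spectrum(uncoupled, isotropic_powder, grid_small, frange, 9.6)

        def pp_width(spec):
            return spec.field_mT[np.argmin(spec.intensity)] - spec.field_mT[
                np.argmax(spec.intensity)
            ]

        assert pp_width(with_c) > pp_width(without)

    def test_truncation_flagged(self, sar1, isotropic_powder, grid_small):
        with pytest.warns(TruncationWarning):
            spec = simulate_cw_spectrum(
                sar1, isotropic_powder, grid_small, (341.0, 343.0, 256), 9.6
            )
        assert spec.truncated


class TestFrequencyRescale:
    def test_known_feature_shift(self):
        from spinpol.types import CWSpectrum

        axis = np.linspace(330.0, 338.0, 101)
        spec = CWSpectrum(axis, np.zeros_like(axis), 9.38611)
        scaled = frequency_rescale(spec, 9.6)
        i = np.argmin(np.abs(axis - 334.0))
        assert scaled.field_mT[i] == pytest.approx(334.0 * 9.6 / 9.38611, rel=1e-12)
        assert scaled.field_mT[i] == pytest.approx(341.61, abs=0.01)

    def test_identity_and_round_trip(self):
        from spinpol.types import CWSpectrum

        spec = CWSpectrum(np.linspace(330, 350, 64), np.ones(64), 9.4)
        assert np.array_equal(frequency_rescale(spec, 9.4).field_mT, spec.field_mT)
        back = frequency_rescale(frequency_rescale(spec, 9.6), 9.4)
        assert np.allclose(back.field_mT, spec.field_mT, rtol=1e-12)

    def test_nonpositive_target_rejected(self):
        from spinpol.types import CWSpectrum

        spec = CWSpectrum(np.linspace(330, 350, 8), np.ones(8), 9.4)
        with pytest.raises(ValidationError):
            frequency_rescale(spec, 0.0)


class TestSpectralDensity:
    @pytest.mark.parametrize("lam", [-5.0, -1.0, 0.0, 1.0, 5.0])
    def test_unit_integral(self, sar1, grid_small, lam):
        gofw = spectral_density(sar1, OrientationDistribution(lam), grid_small, 6.7)
        assert np.trapezoid(gofw.density, gofw.freq_axis_GHz) == pytest.approx(1.0, abs=1e-6)

    def test_single_line_width_equals_kernel(self, grid_small):
        system = SpinSystem(TensorSpec([2.0023] * 3))
        gofw = spectral_density(
            system, OrientationDistribution(0.0), grid_small, 6.7, kernel_fwhm_GHz=0.05
        )
        sigma = 0.05 / (2 * np.sqrt(2 * np.log(2)))
        assert gofw.width_d_GHz == pytest.approx(2 * sigma, rel=0.1)

    def test_g_anisotropy_scales_with_field(self, grid_medium):
        system = SpinSystem(TensorSpec([2.000, 2.003, 2.006]))
        kw = dict(kernel_fwhm_GHz=0.005, npts=4001)
        d1 = spectral_density(system, OrientationDistribution(0.0), grid_medium, 3.35, **kw)
        d2 = spectral_density(system, OrientationDistribution(0.0), grid_medium, 6.7, **kw)
        assert d2.width_d_GHz / d1.width_d_GHz == pytest.approx(2.0, rel=0.02)


class TestComposeComponents:
    def test_single_component_identity(self, narrow_gaussian_density):
        out = compose_components([(1.0, narrow_gaussian_density)])
        assert np.allclose(
            np.interp(
                narrow_gaussian_density.freq_axis_GHz, out.freq_axis_GHz, out.density
            ),
            narrow_gaussian_density.density,
            rtol=1e-6,
            atol=1e-9,
        )

    def test_two_identical_components_identity(self, narrow_gaussian_density):
        out = compose_components(
            [(0.4, narrow_gaussian_density), (0.6, narrow_gaussian_density)]
        )
        ref = np.interp(narrow_gaussian_density.freq_axis_GHz, out.freq_axis_GHz, out.density)
        assert np.allclose(ref, narrow_gaussian_density.density, rtol=1e-6, atol=1e-9)

    def test_disjoint_mass_ratio(self):
        axis1 = np.linspace(186.0, 187.0, 501)
        axis2 = np.linspace(189.0, 190.0, 501)
        d1 = np.exp(-0.5 * ((axis1 - 186.5) / 0.05) ** 2)
        d2 = np.exp(-0.5 * ((axis2 - 189.5) / 0.05) ** 2)
        c1 = spinsim.SpectralDensity(axis1, d1 / np.trapezoid(d1, axis1), 6.7)
        c2 = spinsim.SpectralDensity(axis2, d2 / np.trapezoid(d2, axis2), 6.7)
        out = compose_components([(1.0, c1), (3.0, c2)])
        low = out.freq_axis_GHz < 188.0
        mass_low = np.trapezoid(np.where(low, out.density, 0.0), out.freq_axis_GHz)
        mass_high = np.trapezoid(np.where(~low, out.density, 0.0), out.freq_axis_GHz)
        assert mass_high / mass_low == pytest.approx(3.0, rel=1e-3)

    def test_mismatched_field_rejected(self, narrow_gaussian_density):
        other = spinsim.SpectralDensity(
            narrow_gaussian_density.freq_axis_GHz,
            narrow_gaussian_density.density,
            3.35,
        )
        with pytest.raises(ValidationError):
            compose_components([(1.0, narrow_gaussian_density), (1.0, other)])
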