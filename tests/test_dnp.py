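import numpy as np
import pytest

from spinpol import dnp
from spinpol.exceptions import ValidationError
from spinpol.synthetic import NoiseSpec, gen_buildup
from spinpol.types import CurveSeries

CTX = dnp.DnpContext(b0_T=6.7, temperature_K=1.4)


def test_context_defaults_to_carbon13_larmor():
    assert CTX.nuclear_larmor_MHz == pytest.approx(10.7084 * 6.7, rel=1e-12)


class TestSolidEffect:
    def test_narrow_line_extrema_at_larmor_offsets(self, narrow_gaussian_density):
        profile = dnp.solid_effect_profile(narrow_gaussian_density, CTX)
        nu_n = CTX.nuclear_larmor_MHz / 1e3
        axis = profile.mw_frequency_GHz
        step = axis[1] - axis[0]
        peak_pos = axis[np.argmax(profile.enhancement)]
        peak_neg = axis[np.argmin(profile.enhancement)]
        assert abs(peak_pos - (188.0 - nu_n)) <= step  # positive lobe below the line
        assert abs(peak_neg - (188.0 + nu_n)) <= step

    def test_antisymmetric_for_symmetric_g(self, narrow_gaussian_density):
        profile = dnp.solid_effect_profile(narrow_gaussian_density, CTX)
        axis = profile.mw_frequency_GHz
        mirrored = np.interp(2 * 188.0 - axis, axis, profile.enhancement)
        assert np.max(np.abs(profile.enhancement + mirrored)) < 1e-6
        assert abs(np.trapezoid(profile.enhancement, axis)) < 1e-6 * np.trapezoid(
            np.abs(profile.enhancement), axis
        )

    def test_larmor_beyond_axis_rejected(self, narrow_gaussian_density):
        huge = dnp.DnpContext(b0_T=6.7, nuclear_larmor_MHz=5000.0)
        with pytest.raises(ValidationError):
            dnp.solid_effect_profile(narrow_gaussian_density, huge)


class TestThermalMixing:
    def test_zero_at_barycenter(self, narrow_gaussian_density):
        profile, sols = dnp.thermal_mixing_profile(
            narrow_gaussian_density, CTX, mw_axis_GHz=np.array([188.0])
        )
        # exact zero only in the constant-P_L limit; the residual reflects the
        # slow variation of the lattice polarization across the line
        assert profile.enhancement[0] == pytest.approx(0.0, abs=1e-4)
        assert sols[0].beta_per_K == pytest.approx(0.0, abs=1e-2)

    def test_antisymmetric_and_single_sign_change(self, narrow_gaussian_density):
        mw = np.linspace(187.6, 188.4, 81)
        profile, sols = dnp.thermal_mixing_profile(narrow_gaussian_density, CTX, mw_axis_GHz=mw)
        p = profile.enhancement
        mirrored = np.interp(2 * 188.0 - mw, mw, p)
        assert np.max(np.abs(p + mirrored)) < 1e-4
        signs = np.sign(p[np.abs(p) > 1e-4])
        assert np.count_nonzero(np.diff(signs) != 0) == 1  # bimodal: one zero crossing
        assert np.all(np.abs(p) <= 1.0)

    def test_vanishes_at_high_lattice_temperature(self, narrow_gaussian_density):
        hot = dnp.DnpContext(b0_T=6.7, temperature_K=1e6)
        mw = np.linspace(187.7, 188.3, 13)
        profile, _ = dnp.thermal_mixing_profile(narrow_gaussian_density, hot, mw_axis_GHz=mw)
        assert np.max(np.abs(profile.enhancement)) < 1e-4

    def test_polarization_grows_as_lattice_cools(self, narrow_gaussian_density):
        mw = np.array([187.9])
        cold, _ = dnp.thermal_mixing_profile(
            narrow_gaussian_density, dnp.DnpContext(6.7, 1.4), mw_axis_GHz=mw
        )
        warm, _ = dnp.thermal_mixing_profile(
            narrow_gaussian_density, dnp.DnpContext(6.7, 4.2), mw_axis_GHz=mw
        )
        assert cold.enhancement[0] > warm.enhancement[0] > 0


class TestSweptIrradiation:
    def test_zero_width_identity(self, narrow_gaussian_density):
        profile = dnp.solid_effect_profile(narrow_gaussian_density, CTX)
        out = dnp.swept_irradiation_profile(profile, 0.0)
        assert np.array_equal(out.enhancement, profile.enhancement)

    def test_cancellation_at_antisymmetric_center(self, narrow_gaussian_density):
        profile = dnp.solid_effect_profile(narrow_gaussian_density, CTX)
        nu_n = CTX.nuclear_larmor_MHz / 1e3
        out = dnp.swept_irradiation_profile(profile, 4 * nu_n)
        center = np.argmin(np.abs(profile.mw_frequency_GHz - 188.0))
        assert abs(out.enhancement[center]) < 0.02 * np.abs(profile.enhancement).max()

    def test_rectangle_becomes_trapezoid(self):
        axis = np.linspace(0.0, 1.0, 1001)
        rect = np.where(np.abs(axis - 0.5) <= 0.1, 1.0, 0.0)
        profile = dnp.SweepProfile(axis, rect)
        w = 0.05
        out = dnp.swept_irradiation_profile(profile, w)
        step = axis[1] - axis[0]
        ramp = (np.abs(axis - 0.4) < w / 2 - step) | (np.abs(axis - 0.6) < w / 2 - step)
        flat = np.abs(axis - 0.5) < 0.1 - w
        assert np.allclose(out.enhancement[flat], 1.0, atol=1e-9)
        grad = np.gradient(out.enhancement, axis)
        assert np.allclose(np.abs(grad[ramp]), 1.0 / w, rtol=0.05)

    def test_window_wider_than_axis_rejected(self, narrow_gaussian_density):
        profile = dnp.solid_effect_profile(narrow_gaussian_density, CTX)
        with pytest.raises(ValidationError):
            dnp.swept_irradiation_profile(profile, 10.0)


class TestCrossEffect:
    def test_bimodal_signature(self, narrow_gaussian_density):
        profile = dnp.cross_effect_profile(narrow_gaussian_density, CTX)
        p = profile.enhancement
        signs = np.sign(p[np.abs(p) > 1e-6])
        assert np.count_nonzero(np.diff(signs) != 0) == 1


TABLE_ROWS = {
    # dose-series buildups at 6.7 T: (P, T_s, tau_hr, A)
    "70kGy": (5.11e6, 14.9, 6.88, 0.099),
    "30kGy": (1.52e6, 22.9, 0.92, 0.264),
}


class TestBuildupFit:
    def test_noiseless_round_trip_to_4_digits(self):
        p, t_fast, tau_hr, a = TABLE_ROWS["70kGy"]
        t = np.arange(0.0, 8 * 3600.0, 10.0)
        curve, _ = gen_buildup(p, a, t_fast, tau_hr, t, NoiseSpec(sigma=0.0))
        fit = dnp.fit_buildup(curve, model="bi")
        assert fit.P == pytest.approx(p, rel=1e-4)
        assert fit.A == pytest.approx(a, rel=1e-4)
        assert fit.T_s == pytest.approx(t_fast, rel=1e-4)
        assert fit.tau_hr == pytest.approx(tau_hr, rel=1e-4)
        assert not fit.weakly_identified

    def test_degenerate_fast_only_selects_mono(self):
        t = np.arange(0.0, 600.0, 5.0)
        curve, _ = gen_buildup(100.0, 1.0, 60.0, 60.0 / 3600.0, t, NoiseSpec(sigma=0.005, seed=2))
        fit = dnp.fit_buildup(curve, model="auto")
        assert fit.model == "mono"
        assert fit.T_s == pytest.approx(60.0, rel=0.05)

    def test_mono_trityl_recovery(self):
        t = np.arange(0.0, 7200.0, 30.0)
        curve, _ = gen_buildup(41.0, 1.0, 1653.0, 1653.0 / 3600.0, t, NoiseSpec(sigma=0.01, seed=4))
        fit = dnp.fit_buildup(curve, model="auto")
        assert fit.model == "mono"
        assert fit.T_s == pytest.approx(1653.0, rel=0.05)

    def test_model_selection_consistency(self):
        """Biexponential data with dense early sampling is recognized as
        biexponential in at least 95 of 100 seeded draws."""
        p, t_fast, tau_hr, a = TABLE_ROWS["70kGy"]
        t = np.concatenate([np.arange(0.0, 300.0, 5.0), np.arange(300.0, 8 * 3600.0, 60.0)])
        chosen = 0
        for seed in range(100):
            curve, _ = gen_buildup(p, a, t_fast, tau_hr, t, NoiseSpec(sigma=0.005, seed=seed))
            fit = dnp.fit_buildup(curve, model="auto")
            if fit.model == "bi":
                chosen += 1
        assert chosen >= 95

    def test_weak_identifiability_flag(self):
        t = np.arange(0.0, 2000.0, 5.0)
        curve, _ = gen_buildup(10.0, 0.5, 100.0, 200.0 / 3600.0, t, NoiseSpec(sigma=0.0))
        fit = dnp.fit_buildup(curve, model="bi")
        assert fit.weakly_identified

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            dnp.fit_buildup(CurveSeries([0, 1, 2], [0.0, 1.0, 2.0]))
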