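"""DNP microwave-sweep prediction and polarization-buildup kinetics.

Sweep models operate on a normalized electron spectral density g(omega):

* **Solid effect** -- enhancement proportional to
  g(omega_mw + omega_N) - g(omega_mw - omega_N): extrema near
  omega_e -/+ omega_N, positive lobe when irradiating below the line.
* **Thermal mixing** -- a Borghini/Provotorov stationary spin-temperature
  balance: the non-Zeeman reservoir settles at the inverse spin temperature
  beta solving

      integral g(w) (w - w_mw) [P_L(w) - tanh(u (w - w_mw) s beta)] dw = 0,

  with P_L(w) = tanh(u w / T_L) the electron thermal polarization at lattice
  temperature T_L and u = h/(2 k_B) expressed in K/GHz.  The predicted
  nuclear polarization is tanh(u w_N s beta).  The effective
  electron-nuclear coupling scale s is not derivable from first principles
  here and is exposed as a parameter (default 1).  For any unimodal
  symmetric g this produces the classic bimodal profile with a single zero
  at the line barycenter.
* **Cross effect (heuristic)** -- g(w)[g(w - w_N) - g(w + w_N)], provided
  only to show the bimodality this family of models shares.
* **Swept irradiation** -- first-order model of frequency-modulated
  microwaves as a moving average of the fixed-frequency profile over the
  sweep window.

Buildup curves follow y = P [A (1 - e^(-t/T)) + (1-A)(1 - e^(-t/tau))]
(biexponential; A = 1 collapses to monoexponential), fitted by seeded
multi-start bounded least squares with AICc model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .constants import GAMMA_13C_MHZ_PER_T, h, k_B
from .exceptions import FitError, ValidationError
from .spinsim import SpectralDensity
from .types import CurveSeries

__all__ = [
    "DnpContext",
    "SweepProfile",
    "ThermalMixingSolution",
    "solid_effect_profile",
    "thermal_mixing_profile",
    "cross_effect_profile",
    "swept_irradiation_profile",
    "BuildupFit",
    "BuildupModel",
    "fit_buildup",
]

#: h/(2 k_B) in kelvin per GHz -- converts a frequency offset to the spin-
#: temperature argument of tanh.
_U_K_PER_GHZ = h * 1e9 / (2.0 * k_B)


@dataclass
class DnpContext:
    """Static-field / temperature context for the mechanism models."""

    b0_T: float
    temperature_K: float = 1.4
    nuclear_larmor_MHz: Optional[float] = None
    electron_center_GHz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.b0_T <= 0 or self.temperature_K <= 0:
            raise ValidationError("b0 and temperature must be positive")
        if self.nuclear_larmor_MHz is None:
            self.nuclear_larmor_MHz = GAMMA_13C_MHZ_PER_T * self.b0_T
        if self.nuclear_larmor_MHz <= 0:
            raise ValidationError("nuclear Larmor frequency must be positive")


@dataclass
class SweepProfile:
    """Relative nuclear enhancement versus microwave frequency."""

    mw_frequency_GHz: np.ndarray
    enhancement: np.ndarray
    model: str = ""

    def __post_init__(self) -> None:
        self.mw_frequency_GHz = np.asarray(self.mw_frequency_GHz, dtype=float)
        self.enhancement = np.asarray(self.enhancement, dtype=float)
        if self.mw_frequency_GHz.shape != self.enhancement.shape:
            raise ValidationError("axis and enhancement must have equal length")
        if not np.all(np.isfinite(self.enhancement)):
            raise ValidationError("enhancement values must be finite")


@dataclass
class ThermalMixingSolution:
    beta_per_K: float
    nuclear_polarization: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if abs(self.nuclear_polarization) > 1.0 + 1e-12:
            raise ValidationError("|P_n| cannot exceed 1")


def _center(gofw: SpectralDensity) -> float:
    return gofw.barycenter_GHz


def solid_effect_profile(gofw: SpectralDensity, ctx: DnpContext) -> SweepProfile:
    """Solid-effect sweep profile E(w_mw) = g(w_mw + w_N) - g(w_mw - w_N).

    Normalized to unit maximum |E|; the positive lobe sits at the low-
    frequency side (w_e - w_N) of the line.
    """
    nu_n = ctx.nuclear_larmor_MHz / 1e3
    axis = gofw.freq_axis_GHz
    if nu_n > axis[-1] - axis[0]:
        raise ValidationError("nuclear Larmor frequency exceeds the g(omega) axis span")
    up = np.interp(axis + nu_n, axis, gofw.density, left=0.0, right=0.0)
    down = np.interp(axis - nu_n, axis, gofw.density, left=0.0, right=0.0)
    e = up - down
    peak = np.abs(e).max()
    if peak > 0:
        e = e / peak
    return SweepProfile(axis.copy(), e, model="solid-effect")


def thermal_mixing_profile(
    gofw: SpectralDensity,
    ctx: DnpContext,
    coupling_scale: float = 1.0,
    mw_axis_GHz: Optional[np.ndarray] = None,
) -> tuple[SweepProfile, list[ThermalMixingSolution]]:
    """Borghini-type stationary thermal-mixing sweep profile.

    For each microwave frequency the stationary inverse spin temperature
    beta of the non-Zeeman reservoir is bracketed and solved with Brent's
    method (the balance function is strictly decreasing in beta, so the
    root is unique and the solver deterministic).  Returns the profile of
    predicted nuclear polarizations and the per-frequency solutions.  When
    no sign change exists in the bracket the zero solution is returned,
    flagged.
    """
    axis = gofw.freq_axis_GHz
    dens = gofw.density
    if mw_axis_GHz is None:
        mw_axis_GHz = axis
    mw_axis_GHz = np.asarray(mw_axis_GHz, dtype=float)
    p_lattice = np.tanh(_U_K_PER_GHZ * axis / ctx.temperature_K)
    nu_n = ctx.nuclear_larmor_MHz / 1e3
    s = coupling_scale
    beta_max = 1e4 / ctx.temperature_K  # spin temperatures down to 1e-4 T_L
    solutions: list[ThermalMixingSolution] = []
    p_n = np.empty(mw_axis_GHz.size)
    for i, nu_mw in enumerate(mw_axis_GHz):
        offset = axis - nu_mw

        def balance(beta):
            return np.trapezoid(
                dens * offset * (p_lattice - np.tanh(_U_K_PER_GHZ * offset * s * beta)), axis
            )

        f_lo, f_hi = balance(-beta_max), balance(beta_max)
        if f_lo * f_hi > 0:
            sol = ThermalMixingSolution(0.0, 0.0, flagged=True)
        else:
            beta = optimize.brentq(balance, -beta_max, beta_max, xtol=1e-12, rtol=1e-14)
            sol = ThermalMixingSolution(
                float(beta), float(np.tanh(_U_K_PER_GHZ * nu_n * s * beta))
            )
        solutions.append(sol)
        p_n[i] = sol.nuclear_polarization
    return SweepProfile(mw_axis_GHz.copy(), p_n, model="thermal-mixing"), solutions


def cross_effect_profile(gofw: SpectralDensity, ctx: DnpContext) -> SweepProfile:
    """Heuristic cross-effect shape g(w) [g(w - w_N) - g(w + w_N)].

    Provided to illustrate that cross-effect-type models share the bimodal
    signature of thermal mixing; not a quantitative treatment.
    """
    nu_n = ctx.nuclear_larmor_MHz / 1e3
    axis = gofw.freq_axis_GHz
    down = np.interp(axis - nu_n, axis, gofw.density, left=0.0, right=0.0)
    up = np.interp(axis + nu_n, axis, gofw.density, left=0.0, right=0.0)
    e = gofw.density * (down - up)
    peak = np.abs(e).max()
    if peak > 0:
        e = e / peak
    return SweepProfile(axis.copy(), e, model="cross-effect")


def swept_irradiation_profile(profile: SweepProfile, sweep_width_GHz: float) -> SweepProfile:
    """Moving-average model of frequency-swept microwave irradiation."""
    if sweep_width_GHz < 0:
        raise ValidationError("sweep width must be nonnegative")
    axis = profile.mw_frequency_GHz
    step = axis[1] - axis[0]
    window = int(round(sweep_width_GHz / step)) + 1
    if window <= 1:
        return SweepProfile(axis.copy(), profile.enhancement.copy(), model=profile.model)
    if window > axis.size:
        raise ValidationError("sweep window wider than the profile axis")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(profile.enhancement, kernel, mode="same")
    return SweepProfile(axis.copy(), smoothed, model=f"{profile.model}+swept")


# ------------------------------------------------------------------ buildup

@dataclass
class BuildupFit:
    """Fitted buildup kinetics (T in seconds, tau in hours, as reported)."""

    P: float
    A: float
    T_s: float
    tau_hr: float
    model: str
    aicc: float
    weakly_identified: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.A <= 1:
            raise ValidationError("fast weighting A must be in [0, 1]")
        if self.T_s <= 0 or self.tau_hr <= 0:
            raise ValidationError("time constants must be positive")


def _biexp(t, p, a, t_fast, tau_slow):
    return p * (a * (1.0 - np.exp(-t / t_fast)) + (1.0 - a) * (1.0 - np.exp(-t / tau_slow)))


def _monoexp(t, p, tau):
    return p * (1.0 - np.exp(-t / tau))


def _aicc(resid: np.ndarray, k: int) -> float:
    n = resid.size
    rss = float(np.sum(resid**2))
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


class BuildupModel(BaseEstimator):
    """Mono/biexponential polarization-buildup fit with model selection.

    Parameters
    ----------
    model : "mono" | "bi" | "auto"
        "auto" picks the form with the lower small-sample-corrected AIC.
    n_starts : multi-start count for the biexponential local refinements.
    random_state : seed for the start perturbations.

    Attributes (after fit)
    ----------------------
    P_, A_, T_fast_s_, tau_slow_hr_ : fitted parameters (T < tau enforced;
        for a monoexponential result A_ = 1 and T_fast_s_ carries the single
        time constant, with tau_slow_hr_ its value in hours).
    model_ : selected model; aicc_ : its AICc; weakly_identified_ : True
        when the two time constants differ by less than 3x.
    """

    def __init__(self, model: str = "auto", n_starts: int = 5, random_state: int = 0):
        self.model = model
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 6:
            raise ValidationError("need at least 6 points to fit a buildup")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.model not in ("mono", "bi", "auto"):
            raise ValidationError(f"unknown model {self.model!r}")
        t_span = t[-1] - t[0] if t[-1] > t[0] else 1.0
        scale = max(abs(y).max(), 1e-30)

        mono = self._fit_mono(t, y, t_span, scale)
        bi = None
        if self.model in ("bi", "auto"):
            bi = self._fit_bi(t, y, t_span, scale)
        if self.model == "mono" or (self.model == "auto" and (bi is None or mono[1] <= bi[1])):
            (p, tau), aicc = mono[0], mono[1]
            self.model_, self.P_, self.A_ = "mono", float(p), 1.0
            self.T_fast_s_ = float(tau)
            self.tau_slow_hr_ = float(tau) / 3600.0
            self.weakly_identified_ = False
        else:
            if bi is None:
                raise FitError("biexponential fit failed from all starts")
            (p, a, t_fast, tau_slow), aicc = bi[0], bi[1]
            self.model_, self.P_, self.A_ = "bi", float(p), float(a)
            self.T_fast_s_ = float(t_fast)
            self.tau_slow_hr_ = float(tau_slow) / 3600.0
            self.weakly_identified_ = bool(tau_slow / t_fast < 3.0)
        self.aicc_ = float(aicc)
        self.result_ = BuildupFit(
            self.P_, self.A_, self.T_fast_s_, self.tau_slow_hr_, self.model_, self.aicc_,
            self.weakly_identified_,
        )
        return self

    def _fit_mono(self, t, y, t_span, scale):
        best = None
        for tau0 in (t_span / 30.0, t_span / 3.0, t_span):
            try:
                popt, _ = optimize.curve_fit(
                    _monoexp, t, y, p0=[scale, tau0],
                    bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
                )
            except RuntimeError:
                continue
            aicc = _aicc(y - _monoexp(t, *popt), 2)
            if best is None or aicc < best[1]:
                best = (popt, aicc)
        if best is None:
            raise FitError("monoexponential fit failed from all starts")
        return best

    def _fit_bi(self, t, y, t_span, scale):
        rng = np.random.default_rng(self.random_state)
        lower = [0.0, 0.0, 1e-9, 1e-9]
        upper = [np.inf, 1.0, np.inf, np.inf]
        starts = [(scale, 0.2, t_span / 300.0, t_span / 2.0)]
        for _ in range(max(self.n_starts - 1, 0)):
            starts.append(
                (
                    scale * rng.uniform(0.5, 2.0),
                    rng.uniform(0.05, 0.95),
                    t_span * 10 ** rng.uniform(-3.5, -1.0),
                    t_span * 10 ** rng.uniform(-1.0, 0.7),
                )
            )
        best = None
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(
                    _biexp, t, y, p0=list(p0), bounds=(lower, upper), maxfev=40000
                )
            except RuntimeError:
                continue
            p, a, t1, t2 = popt
            if t1 > t2:  # enforce T < tau by swapping branches
                t1, t2, a = t2, t1, 1.0 - a
            aicc = _aicc(y - _biexp(t, p, a, t1, t2), 4)
            if best is None or aicc < best[1]:
                best = ((p, a, t1, t2), aicc)
        return best

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.model_ == "mono":
            return _monoexp(t, self.P_, self.T_fast_s_)
        return _biexp(t, self.P_, self.A_, self.T_fast_s_, self.tau_slow_hr_ * 3600.0)


def fit_buildup(curve: CurveSeries, model: str = "auto") -> BuildupFit:
    """Fit buildup kinetics to a CurveSeries; see :class:`BuildupModel`."""
    return BuildupModel(model=model).fit(curve.t, curve.y).result_
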