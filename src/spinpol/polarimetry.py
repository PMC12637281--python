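"""Polarization, enhancement and liquid-state T1 from benchtop NMR decays.

A hyperpolarized liquid sampled with repeated small-angle pulses yields

    s_n = M1 sin(theta) cos(theta)^(n-1) exp(-(n-1) TR / T1),  n = 1, 2, ...

where M1 is the longitudinal magnetization at the first pulse: each pulse
reads out sin(theta) of the magnetization and leaves cos(theta) of it,
while T1 relaxes the remainder toward (negligible) thermal equilibrium
between pulses.  Fitting this model separates the flip-angle depletion
from the true T1 decay.  Back-extrapolation multiplies the polarization at
the first acquisition by exp(+elapsed/T1) to recover the value at
dissolution, treating the delay as pure T1 decay (no transfer losses).

The enhancement factor is the measured polarization over the thermal
two-level polarization tanh(h nu / 2 k_B T) at the detection field and
sample temperature (default 300 K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .constants import GAMMA_13C_MHZ_PER_T, h, k_B
from .exceptions import FitError, ValidationError
from .types import CurveSeries

__all__ = [
    "thermal_polarization",
    "enhancement_factor",
    "PolarizationResult",
    "DecayFit",
    "FlipAngleDecayModel",
    "fit_decay",
    "back_extrapolate",
]


def thermal_polarization(
    b0_T: float, temperature_K: float, gamma_over_2pi_MHz_per_T: float = GAMMA_13C_MHZ_PER_T
) -> float:
    """Thermal two-level nuclear polarization tanh(h nu / 2 k_B T)."""
    if b0_T < 0 or temperature_K <= 0 or gamma_over_2pi_MHz_per_T <= 0:
        raise ValidationError("field must be >= 0; temperature and gamma positive")
    nu_Hz = gamma_over_2pi_MHz_per_T * 1e6 * b0_T
    return float(np.tanh(h * nu_Hz / (2.0 * k_B * temperature_K)))


@dataclass
class PolarizationResult:
    P: float
    P_thermal: float
    epsilon: float
    b0_T: float
    temperature_K: float

    def __post_init__(self) -> None:
        if self.epsilon < 0 or not 0 < self.P_thermal < 1:
            raise ValidationError("invalid polarization result")


def enhancement_factor(
    P: float,
    b0_T: float,
    temperature_K: float = 300.0,
    gamma_over_2pi_MHz_per_T: float = GAMMA_13C_MHZ_PER_T,
) -> PolarizationResult:
    """Enhancement epsilon = P / P_thermal(b0, T)."""
    if not 0 <= P <= 1:
        raise ValidationError("polarization fraction must be in [0, 1]")
    p_th = thermal_polarization(b0_T, temperature_K, gamma_over_2pi_MHz_per_T)
    return PolarizationResult(P, p_th, P / p_th, b0_T, temperature_K)


# ------------------------------------------------------------------ decay

@dataclass
class DecayFit:
    """Fitted flip-angle-sampled decay: signal amplitude, T1 and context."""

    S0: float
    T1_s: float
    flip_angle_deg: float
    tr_s: float
    P0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.T1_s <= 0:
            raise ValidationError("T1 must be positive")
        if self.P0 is not None and not 0 <= self.P0 <= 1:
            raise ValidationError("P0 must be a fraction in [0, 1]")


class FlipAngleDecayModel(BaseEstimator):
    """Fit of s_n = S0 sin(theta) cos(theta)^(n-1) e^(-(n-1)TR/T1).

    Parameters
    ----------
    flip_angle_deg : readout flip angle theta, 0 < theta < 90
    tr_s : repetition time between pulses

    Attributes (after fit)
    ----------------------
    S0_ : longitudinal magnetization (polarization units of the input) at
        the first pulse
    T1_s_ : longitudinal relaxation time, flip-angle depletion removed
    apparent_T1_s_ : decay time of the raw signal envelope (flip-angle
        depletion still included), for comparison
    """

    def __init__(self, flip_angle_deg: float, tr_s: float):
        self.flip_angle_deg = flip_angle_deg
        self.tr_s = tr_s

    def fit(self, t, y):
        if not 0 < self.flip_angle_deg < 90:
            raise ValidationError("flip angle must be in (0, 90) degrees")
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 5:
            raise ValidationError("need at least 5 acquisitions")
        steps = np.diff(t)
        if np.max(np.abs(steps - self.tr_s)) > 1e-6 * self.tr_s:
            raise ValidationError("acquisitions must be uniformly spaced at TR")
        theta = np.radians(self.flip_angle_deg)
        n = np.arange(t.size)  # n - 1 with the first pulse at index 0
        log_cos = np.log(np.cos(theta))

        def model(nn, s0, t1):
            return s0 * np.sin(theta) * np.exp(nn * (log_cos - self.tr_s / t1))

        # log-linear init on the positive part of the envelope
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(n[pos], np.log(y[pos]), 1)
            rate = self.tr_s / max(-(slope - log_cos), 1e-12)
            s0_init = np.exp(intercept) / np.sin(theta)
        else:
            raise FitError("decay series has fewer than 2 positive samples")
        try:
            popt, _ = optimize.curve_fit(
                model, n, y, p0=[s0_init, min(rate, 1e7)],
                bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError as err:  # pragma: no cover
            raise FitError(f"decay fit did not converge: {err}") from err
        self.S0_, self.T1_s_ = float(popt[0]), float(popt[1])
        # apparent rate includes the per-pulse cos(theta) depletion
        self.apparent_T1_s_ = float(1.0 / (1.0 / self.T1_s_ - log_cos / self.tr_s))
        self.result_ = DecayFit(self.S0_, self.T1_s_, self.flip_angle_deg, self.tr_s)
        return self

    def back_extrapolate(self, elapsed_s: float) -> float:
        """Polarization at ``elapsed_s`` before the first acquisition."""
        return back_extrapolate(self.result_, elapsed_s)


def fit_decay(series: CurveSeries, flip_angle_deg: float, tr_s: float) -> DecayFit:
    """Fit the flip-angle-corrected decay model to a sampled series."""
    est = FlipAngleDecayModel(flip_angle_deg, tr_s).fit(series.t, series.y)
    return est.result_


def back_extrapolate(fit: DecayFit, elapsed_s: float) -> float:
    """Polarization at dissolution: P_measured * exp(+elapsed/T1).

    Flip-angle losses before the first acquisition are excluded by
    convention; the delay between dissolution and first pulse is treated as
    pure T1 decay.
    """
    if elapsed_s < 0:
        raise ValidationError("elapsed time must be nonnegative")
    return float(fit.S0 * np.exp(elapsed_s / fit.T1_s))
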