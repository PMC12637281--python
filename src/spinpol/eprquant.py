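"""Spin quantification from CW-EPR spectra.

The spin count of a sample is proportional to the double integral of its
baseline-corrected first-derivative spectrum, after normalizing out
instrument factors (resonator Q, receiver gain, modulation amplitude,
sqrt(microwave power), sample mass).  Absolute concentrations come from a
calibration line through the origin against standards of known
concentration (TEMPO).  The module also fits saturating dose-response
curves N(D) = N_inf (1 - exp(-D/D_c)) for radiation-generated radicals and
tests longitudinal stability of stored samples by an OLS trend with a
t-based confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import FitError, ValidationError
from .types import CWSpectrum

__all__ = [
    "baseline_correct",
    "double_integrate",
    "normalize_integral",
    "SpinCountResult",
    "SpinCountCalibration",
    "calibrate_spin_count",
    "DoseResponseModel",
    "fit_dose_response",
    "StabilityTrend",
    "stability_trend",
]

log = logging.getLogger(__name__)


@dataclass
class SpinCountResult:
    raw_double_integral: float
    normalized_integral: float
    spins_mM: Optional[float] = None
    calibration_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.spins_mM is not None and self.spins_mM < 0:
            raise ValidationError("spin count must be nonnegative")


def baseline_correct(
    spectrum: CWSpectrum, poly_order: int = 1, margin_fraction: float = 0.1
) -> CWSpectrum:
    """Subtract a polynomial baseline fitted on the signal-free margins.

    The polynomial is fitted only on the first and last ``margin_fraction``
    of the sweep (the caller guarantees those margins contain no signal) and
    subtracted everywhere.
    """
    if not 0 < margin_fraction <= 0.5:
        raise ValidationError("margin_fraction must be in (0, 0.5]")
    n = spectrum.field_mT.size
    m = max(int(round(margin_fraction * n)), 1)
    idx = np.r_[0:m, n - m : n]
    if poly_order >= idx.size:
        raise ValidationError(f"poly_order {poly_order} >= {idx.size} margin points")
    coeffs = np.polynomial.polynomial.polyfit(
        spectrum.field_mT[idx], spectrum.intensity[idx], poly_order
    )
    baseline = np.polynomial.polynomial.polyval(spectrum.field_mT, coeffs)
    return spectrum.replace(intensity=spectrum.intensity - baseline)


def double_integrate(spectrum: CWSpectrum) -> float:
    """Double integral of a first-derivative spectrum (a.u. mT^2).

    First cumulative-trapezoid integration recovers the absorption line;
    a second trapezoid integration gives the quantity proportional to the
    number of spins.
    """
    if spectrum.field_mT.size < 3:
        raise ValidationError("need at least 3 points to double-integrate")
    absorption = integrate.cumulative_trapezoid(
        spectrum.intensity, spectrum.field_mT, initial=0.0
    )
    return float(np.trapezoid(absorption, spectrum.field_mT))


def normalize_integral(
    raw: float,
    *,
    q_factor: Optional[float] = None,
    receiver_gain: Optional[float] = None,
    modulation_amplitude_mT: Optional[float] = None,
    mw_power_mW: Optional[float] = None,
    sample_mass_mg: Optional[float] = None,
) -> float:
    """Divide out instrument factors from a raw double integral.

    Factors supplied as None are skipped with a logged notice; supplying no
    factor at all is an error.  Power enters as its square root (CW signal
    scales with sqrt(P) below saturation).
    """
    factors = {
        "q_factor": q_factor,
        "receiver_gain": receiver_gain,
        "modulation_amplitude_mT": modulation_amplitude_mT,
        "mw_power_mW": mw_power_mW,
        "sample_mass_mg": sample_mass_mg,
    }
    if all(v is None for v in factors.values()):
        raise ValidationError("no normalization factors supplied")
    value = float(raw)
    for name, factor in factors.items():
        if factor is None:
            log.info("normalize_integral: %s absent, factor skipped", name)
            continue
        if factor <= 0:
            raise ValidationError(f"{name} must be positive, got {factor}")
        value /= np.sqrt(factor) if name == "mw_power_mW" else factor
    return value


def spin_count(
    spectrum: CWSpectrum,
    calibration: Optional["SpinCountCalibration"] = None,
    poly_order: int = 1,
    margin_fraction: float = 0.1,
    mw_power_mW: Optional[float] = None,
) -> SpinCountResult:
    """Baseline-correct, double-integrate, normalize and (optionally)
    convert to a concentration through a fitted calibration."""
    corrected = baseline_correct(spectrum, poly_order, margin_fraction)
    raw = double_integrate(corrected)
    normalized = normalize_integral(
        raw,
        q_factor=spectrum.q_factor,
        receiver_gain=spectrum.receiver_gain,
        modulation_amplitude_mT=spectrum.modulation_amplitude_mT,
        mw_power_mW=mw_power_mW,
        sample_mass_mg=spectrum.sample_mass_mg,
    )
    spins = None
    cal_id = None
    if calibration is not None:
        spins = float(max(calibration.predict([normalized])[0], 0.0))
        cal_id = calibration.calibration_id
    return SpinCountResult(raw, normalized, spins, cal_id)


# ------------------------------------------------------------- calibration

class SpinCountCalibration(BaseEstimator):
    """Concentration calibration line through the origin.

    Fit normalized double integrals against standards of known concentration
    (mM); the regression is forced through zero because zero concentration
    must give zero signal after baseline correction.

    Attributes (after fit)
    ----------------------
    slope_ : a.u. per mM
    slope_se_ : standard error of the slope
    flagged_standards_ : indices of standards with negative integrals
        (accepted but flagged).
    """

    def __init__(self, calibration_id: str = "tempo"):
        self.calibration_id = calibration_id

    def fit(self, concentrations_mM, integrals):
        c = np.asarray(concentrations_mM, dtype=float)
        y = np.asarray(integrals, dtype=float)
        if c.size < 2:
            raise ValidationError("need at least 2 calibration standards")
        if np.allclose(c, c[0]):
            raise ValidationError("calibration standards must span distinct concentrations")
        self.flagged_standards_ = np.nonzero(y < 0)[0].tolist()
        self.slope_ = float(np.sum(c * y) / np.sum(c * c))
        resid = y - self.slope_ * c
        dof = max(c.size - 1, 1)
        self.slope_se_ = float(np.sqrt(np.sum(resid**2) / dof / np.sum(c * c)))
        if self.slope_ <= 0:
            raise FitError("calibration slope is not positive")
        return self

    def predict(self, integrals):
        """Concentration (mM) for normalized integrals."""
        return np.asarray(integrals, dtype=float) / self.slope_


def calibrate_spin_count(standards) -> SpinCountCalibration:
    """Fit a calibration from ``[(concentration_mM, normalized_integral), ...]``."""
    conc, integ = zip(*standards)
    return SpinCountCalibration().fit(conc, integ)


# ------------------------------------------------------------ dose response

class DoseResponseModel(BaseEstimator):
    """Saturating-exponential radical dose response N(D) = N_inf (1 - e^-D/Dc).

    Attributes (after fit): ``n_inf_``, ``d_c_kGy_``, ``residual_norm_``,
    ``poorly_specified_`` (True when the data are not increasing with dose so
    a positive characteristic dose is not supported), and
    ``fraction_of_plateau_at_70_kGy_``.
    """

    def fit(self, doses_kGy, counts):
        d = np.asarray(doses_kGy, dtype=float)
        y = np.asarray(counts, dtype=float)
        if np.unique(d).size < 3:
            raise ValidationError("need at least 3 distinct doses")
        if d.min() > 5.0:
            raise ValidationError("dose series must include 0 or a near-zero dose")
        slope = stats.linregress(d, y).slope
        self.poorly_specified_ = bool(slope <= 0)
        scale = max(abs(y).max(), 1e-30)

        def model(dd, n_inf, d_c):
            return n_inf * (1.0 - np.exp(-dd / d_c))

        try:
            popt, _ = optimize.curve_fit(
                model,
                d,
                y,
                p0=[scale, max(d.max() / 3.0, 1.0)],
                bounds=([1e-12, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as err:  # pragma: no cover - pathological data
            raise FitError(f"dose-response fit did not converge: {err}") from err
        self.n_inf_, self.d_c_kGy_ = float(popt[0]), float(popt[1])
        self.residual_norm_ = float(np.linalg.norm(y - model(d, *popt)))
        self.fraction_of_plateau_at_70_kGy_ = float(1.0 - np.exp(-70.0 / self.d_c_kGy_))
        return self

    def predict(self, doses_kGy):
        return self.n_inf_ * (1.0 - np.exp(-np.asarray(doses_kGy, float) / self.d_c_kGy_))


def fit_dose_response(doses_kGy, counts) -> DoseResponseModel:
    return DoseResponseModel().fit(doses_kGy, counts)


# ---------------------------------------------------------------- stability

class StabilityTrend(BaseEstimator):
    """OLS slope of spin count versus storage time with a t-based CI.

    The sample is flagged ``stable_`` when the two-sided (1-alpha) confidence
    interval for the slope contains zero.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, times_weeks, counts):
        t = np.asarray(times_weeks, dtype=float)
        y = np.asarray(counts, dtype=float)
        if t.size < 3:
            raise ValidationError("need at least 3 time points")
        res = stats.linregress(t, y)
        dof = t.size - 2
        tcrit = stats.t.ppf(1.0 - self.alpha / 2.0, dof)
        self.slope_ = float(res.slope)
        self.slope_se_ = float(res.stderr)
        half = tcrit * res.stderr
        self.ci_ = (self.slope_ - half, self.slope_ + half)
        self.stable_ = bool(self.ci_[0] <= 0.0 <= self.ci_[1])
        self.p_value_ = float(res.pvalue)
        return self


def stability_trend(times_weeks, counts, alpha: float = 0.05) -> StabilityTrend:
    return StabilityTrend(alpha=alpha).fit(times_weeks, counts)
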