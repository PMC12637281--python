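"""Core data containers shared by the IO, simulation and quantification layers.

Fields are stored in the package's internal units (mT, GHz, kHz, s, ppm); the
IO layer converts on ingest so that no downstream code ever sees Gauss or Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ValidationError

__all__ = ["CWSpectrum", "CurveSeries", "SpectrumTimeSeries"]


@dataclass
class CWSpectrum:
    """A field-swept continuous-wave EPR spectrum (first derivative).

    Parameters
    ----------
    field_mT : array
        Magnetic field per point, strictly increasing with a uniform step.
    intensity : array
        First-derivative amplitude (arbitrary units), same length as the axis.
    mw_frequency_GHz : float
        Microwave frequency of the acquisition.
    modulation_frequency_kHz, modulation_amplitude_mT, sweep_rate_mT_s,
    q_factor, receiver_gain, sample_mass_mg : optional acquisition metadata.
    """

    field_mT: np.ndarray
    intensity: np.ndarray
    mw_frequency_GHz: float
    modulation_frequency_kHz: Optional[float] = None
    modulation_amplitude_mT: Optional[float] = None
    sweep_rate_mT_s: Optional[float] = None
    q_factor: Optional[float] = None
    receiver_gain: Optional[float] = None
    sample_mass_mg: Optional[float] = None
    label: str = ""
    truncated: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.field_mT = np.asarray(self.field_mT, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field_mT.ndim != 1 or self.field_mT.size < 2:
            raise ValidationError("field axis must be 1-D with at least 2 points")
        if self.field_mT.shape != self.intensity.shape:
            raise ValidationError("field axis and intensity must have equal length")
        steps = np.diff(self.field_mT)
        if np.any(steps <= 0):
            raise ValidationError("field axis must be strictly increasing")
        step = steps.mean()
        if np.max(np.abs(steps - step)) > 1e-9 * max(abs(step), 1e-30):
            raise ValidationError("field axis step must be uniform to 1e-9 relative")
        if not self.mw_frequency_GHz > 0:
            raise ValidationError("mw_frequency_GHz must be positive")

    @property
    def field_step_mT(self) -> float:
        return float(np.diff(self.field_mT).mean())

    def replace(self, **changes) -> "CWSpectrum":
        return replace(self, **changes)


@dataclass
class CurveSeries:
    """A generic sampled curve y(t) with free-form metadata."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValidationError("t and y must be 1-D arrays of equal length")
        if np.any(self.t < 0):
            raise ValidationError("time values must be nonnegative")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("time values must be nondecreasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class SpectrumTimeSeries:
    """A stack of MRS spectra (frames x points) on a common ppm axis."""

    ppm_axis: np.ndarray
    frames: np.ndarray
    frame_times: np.ndarray
    flip_angle_deg: float = 30.0
    tr_s: float = 3.0

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        d = np.diff(self.ppm_axis)
        if self.ppm_axis.ndim != 1 or not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be monotone")
        if self.frames.shape[0] != self.frame_times.size:
            raise ValidationError("frame count must equal frame_times length")
        if self.frames.shape[1] != self.ppm_axis.size:
            raise ValidationError("each frame must match the ppm axis length")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]
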