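"""Field-swept CW-EPR simulation and electron spectral densities.

The simulator handles S=1/2 radicals with anisotropic g and hyperfine
tensors.  Line positions come from exact diagonalization of each
electron-nucleus pair block (dimension 2(2I+1), including the nuclear
Zeeman term), combined additively across nuclei -- the standard
independent-nucleus approximation, which is accurate to well below the
linewidth for couplings up to ~100 MHz at X-band.  Powder averages use a
deterministic golden-spiral equal-area grid over the hemisphere; partial
molecular ordering enters through the axial orientation distribution

    p(alpha) = exp[-lambda (3 cos^2 alpha - 1)/2],

where alpha is the angle between the molecular z axis and B0 and lambda is
the order parameter (lambda = 0 is an isotropic powder, lambda > 0 favors
alpha = pi/2, lambda < 0 favors the pole).

Euler angles follow the active z-y-z convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import GYROMAGNETIC_MHZ_PER_T, MU_B_MHZ_PER_MT
from .exceptions import TruncationWarning, ValidationError
from .types import CWSpectrum

__all__ = [
    "TensorSpec",
    "NucleusCoupling",
    "LineBroadening",
    "SpinSystem",
    "OrientationDistribution",
    "OrientationGrid",
    "SpectralDensity",
    "euler_zyz",
    "order_weight",
    "golden_spiral_grid",
    "resonance_lines",
    "simulate_cw_spectrum",
    "frequency_rescale",
    "spectral_density",
    "compose_components",
    "carbon13_sar1",
]


# ------------------------------------------------------------------ algebra

def euler_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active z-y-z rotation matrix R = Rz(alpha) Ry(beta) Rz(gamma)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz_a = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry_b = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rz_g = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return rz_a @ ry_b @ rz_g


def spin_operators(s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian spin matrices (Sx, Sy, Sz) for spin quantum number ``s``."""
    n = int(round(2 * s)) + 1
    m = s - np.arange(n)
    sz = np.diag(m).astype(complex)
    sp = np.zeros((n, n), dtype=complex)
    for i in range(1, n):
        sp[i - 1, i] = np.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    sx = (sp + sp.conj().T) / 2
    sy = (sp - sp.conj().T) / 2j
    return sx, sy, sz


# ------------------------------------------------------------------ types

@dataclass
class TensorSpec:
    """Principal values plus z-y-z Euler angles rotating the tensor frame
    into the molecular frame (MHz for hyperfine, dimensionless for g)."""

    principal_values: Sequence[float]
    euler_angles: Sequence[float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.principal_values = np.asarray(self.principal_values, dtype=float)
        self.euler_angles = np.asarray(self.euler_angles, dtype=float)
        if self.principal_values.shape != (3,):
            raise ValidationError("a tensor needs exactly three principal values")
        if self.euler_angles.shape != (3,) or not np.all(np.isfinite(self.euler_angles)):
            raise ValidationError("euler_angles must be three finite numbers")

    def matrix(self) -> np.ndarray:
        """Full 3x3 tensor in the molecular frame."""
        r = euler_zyz(*self.euler_angles)
        return r @ np.diag(self.principal_values) @ r.T

    @property
    def isotropic(self) -> float:
        return float(np.mean(self.principal_values))


@dataclass
class NucleusCoupling:
    """A hyperfine-coupled nucleus: isotope label, spin I, A tensor (MHz)."""

    isotope: str
    I: float
    tensor: TensorSpec

    def __post_init__(self) -> None:
        two_i = 2 * self.I
        if self.I <= 0 or abs(two_i - round(two_i)) > 1e-12:
            raise ValidationError(f"nuclear spin I={self.I} must be a positive half-integer")

    @property
    def gamma_MHz_per_mT(self) -> float:
        return GYROMAGNETIC_MHZ_PER_T.get(self.isotope, 0.0) * 1e-3


@dataclass
class LineBroadening:
    shape: str = "pseudo-voigt"  # gaussian | lorentzian | pseudo-voigt
    fwhm_mT: float = 0.8
    gauss_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm_mT <= 0:
            raise ValidationError("line broadening fwhm must be positive")
        if self.shape not in ("gaussian", "lorentzian", "pseudo-voigt"):
            raise ValidationError(f"unknown line shape {self.shape!r}")

    @property
    def effective_gauss_fraction(self) -> float:
        return {"gaussian": 1.0, "lorentzian": 0.0}.get(self.shape, self.gauss_fraction)


@dataclass
class SpinSystem:
    """Electron S=1/2 with a g tensor and a list of hyperfine couplings."""

    g: TensorSpec
    couplings: list[NucleusCoupling] = field(default_factory=list)
    line_broadening: LineBroadening = field(default_factory=LineBroadening)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError("species weight must be nonnegative")


@dataclass
class OrientationDistribution:
    """Axial ordering of the molecular z axis relative to B0, parameter lambda."""

    lambda_order: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_order):
            raise ValidationError("order parameter must be finite")


@dataclass
class OrientationGrid:
    """(theta, phi) orientations of B0 in the molecular frame with weights."""

    theta: np.ndarray
    phi: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.theta.shape == self.phi.shape == self.weights.shape):
            raise ValidationError("theta, phi, weights must have equal shapes")
        if np.any(self.weights <= 0):
            raise ValidationError("quadrature weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("quadrature weights must sum to 1")

    @property
    def n_vecs(self) -> np.ndarray:
        st = np.sin(self.theta)
        return np.stack([st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)], axis=1)

    def __len__(self) -> int:
        return self.theta.size


@dataclass
class SpectralDensity:
    """Normalized electron resonance-frequency distribution g(omega) at b0."""

    freq_axis_GHz: np.ndarray
    density: np.ndarray
    b0_T: float
    width_d_GHz: float = 0.0

    def __post_init__(self) -> None:
        self.freq_axis_GHz = np.asarray(self.freq_axis_GHz, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freq_axis_GHz.shape != self.density.shape:
            raise ValidationError("axis and density must have equal length")
        if np.any(np.diff(self.freq_axis_GHz) <= 0):
            raise ValidationError("frequency axis must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValidationError("density must be nonnegative")
        integral = np.trapezoid(self.density, self.freq_axis_GHz)
        if abs(integral - 1.0) > 1e-6:
            raise ValidationError(f"density must integrate to 1 (got {integral:.8f})")

    @property
    def barycenter_GHz(self) -> float:
        return float(np.trapezoid(self.freq_axis_GHz * self.density, self.freq_axis_GHz))


# ------------------------------------------------------------------ ordering

def order_weight(alpha, lambda_order):
    """Orientation weight p(alpha) = exp[-lambda (3 cos^2 alpha - 1)/2]."""
    alpha = np.asarray(alpha, dtype=float)
    return np.exp(-lambda_order * (3.0 * np.cos(alpha) ** 2 - 1.0) / 2.0)


def golden_spiral_grid(n: int = 10000) -> OrientationGrid:
    """Deterministic equal-area golden-spiral grid on the upper hemisphere."""
    if n < 1:
        raise ValidationError("grid needs at least one point")
    i = np.arange(n)
    cos_theta = (i + 0.5) / n  # uniform in cos(theta) over (0, 1]
    theta = np.arccos(cos_theta)
    golden = (1 + np.sqrt(5)) / 2
    phi = (2 * np.pi * i / golden) % (2 * np.pi)
    return OrientationGrid(theta, phi, np.full(n, 1.0 / n))


# ------------------------------------------------------------------ resonances

def _pair_block_operators(system: SpinSystem, coupling: NucleusCoupling):
    """Spin operators and the field-independent hyperfine block for one nucleus."""
    sx, sy, sz = spin_operators(0.5)
    ix, iy, iz = spin_operators(coupling.I)
    dim = ix.shape[0]
    s_ops = [np.kron(op, np.eye(dim)) for op in (sx, sy, sz)]
    i_ops = [np.kron(np.eye(2), op) for op in (ix, iy, iz)]
    amat = coupling.tensor.matrix()
    hf = sum(amat[k, l] * (s_ops[k] @ i_ops[l]) for k in range(3) for l in range(3))
    return s_ops, i_ops, hf, dim


def _zeeman_units(system: SpinSystem, n_vecs: np.ndarray, s_ops, i_ops, gamma_n):
    """Per-orientation field-proportional Hamiltonian (MHz per mT)."""
    gmat = system.g.matrix()
    c = n_vecs @ gmat  # symmetric tensor: row vector n^T g
    unit = MU_B_MHZ_PER_MT * np.einsum("nk,kab->nab", c, np.asarray(s_ops))
    if gamma_n:
        unit = unit - gamma_n * np.einsum("nk,kab->nab", n_vecs, np.asarray(i_ops))
    geff = np.linalg.norm(c, axis=1)
    return unit, geff


def _perpendicular_ops(n_vecs: np.ndarray, s_ops) -> tuple[np.ndarray, np.ndarray]:
    """Electron spin operators along two lab axes perpendicular to B0."""
    z = np.zeros_like(n_vecs)
    z[:, 2] = 1.0
    e1 = np.cross(n_vecs, z)
    near_pole = np.linalg.norm(e1, axis=1) < 1e-8
    e1[near_pole] = [1.0, 0.0, 0.0]
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n_vecs, e1)
    s_arr = np.asarray(s_ops)
    return (np.einsum("nk,kab->nab", e1, s_arr), np.einsum("nk,kab->nab", e2, s_arr))


def _nucleus_resonances(system, coupling, n_vecs, nu_GHz, iters=4):
    """Resonance fields (mT) and intensities for one electron-nucleus block.

    Returns arrays of shape (n_orientations, (2I+1)^2): one entry per pair of
    nuclear sublevels in the two electron manifolds, solved by Newton
    iteration on the exact pair-block eigenvalues.
    """
    s_ops, i_ops, hf, dim = _pair_block_operators(system, coupling)
    unit, geff = _zeeman_units(system, n_vecs, s_ops, i_ops, coupling.gamma_MHz_per_mT)
    nu_MHz = nu_GHz * 1e3
    b_free = nu_MHz / (MU_B_MHZ_PER_MT * geff)
    n = n_vecs.shape[0]
    pairs = [(i, dim + f) for i in range(dim) for f in range(dim)]
    slope = MU_B_MHZ_PER_MT * geff  # MHz per mT, Zeeman-dominated
    fields = np.tile(b_free[:, None], (1, len(pairs)))
    op1, op2 = _perpendicular_ops(n_vecs, s_ops)
    intensities = np.empty_like(fields)
    for p, (lo, hi) in enumerate(pairs):
        b = fields[:, p]
        for _ in range(iters):
            h = b[:, None, None] * unit + hf
            w = np.linalg.eigvalsh(h)
            b = b + (nu_MHz - (w[:, hi] - w[:, lo])) / slope
        fields[:, p] = b
        h = b[:, None, None] * unit + hf
        w, v = np.linalg.eigh(h)
        vi, vf = v[:, :, lo], v[:, :, hi]
        m1 = np.einsum("nd,nde,ne->n", vf.conj(), op1, vi)
        m2 = np.einsum("nd,nde,ne->n", vf.conj(), op2, vi)
        intensities[:, p] = (np.abs(m1) ** 2 + np.abs(m2) ** 2) / 2.0
    return fields, intensities, b_free


def _system_resonances(system, n_vecs, nu_GHz, iters=4):
    """All resonance fields/intensities of a SpinSystem for a batch of
    orientations, combining nuclei additively (independent-nucleus model)."""
    gmat = system.g.matrix()
    c = n_vecs @ gmat
    geff = np.linalg.norm(c, axis=1)
    b_free = nu_GHz * 1e3 / (MU_B_MHZ_PER_MT * geff)
    n = n_vecs.shape[0]
    if not system.couplings:
        return b_free[:, None], np.full((n, 1), 0.5)
    fields = b_free[:, None]
    intens = np.ones((n, 1))
    for coupling in system.couplings:
        bp, ip, b0 = _nucleus_resonances(system, coupling, n_vecs, nu_GHz, iters)
        shift = bp - b0[:, None]
        fields = (fields[:, :, None] + shift[:, None, :]).reshape(n, -1)
        intens = (intens[:, :, None] * ip[:, None, :]).reshape(n, -1)
    return fields, intens


def resonance_lines(system: SpinSystem, orientation, mw_frequency_GHz: float):
    """Resonance fields for one orientation of B0 in the molecular frame.

    Parameters
    ----------
    orientation : (theta, phi) in rad
    mw_frequency_GHz : microwave frequency

    Returns a list of ``(field_mT, intensity)`` sorted by field, one line per
    combination of nuclear spin projections (weak forbidden lines included
    when their transition moment is non-negligible).
    """
    if not mw_frequency_GHz > 0:
        raise ValidationError("mw_frequency_GHz must be positive")
    theta, phi = orientation
    n_vec = np.array([[np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]])
    fields, intens = _system_resonances(system, n_vec, mw_frequency_GHz)
    fields, intens = fields[0], intens[0]
    keep = intens > 1e-6 * intens.max()
    order = np.argsort(fields[keep])
    return list(zip(fields[keep][order], intens[keep][order]))


# ------------------------------------------------------------------ spectra

def _kernel_derivative(step_mT: float, broadening: LineBroadening, max_len: int) -> np.ndarray:
    """Sampled derivative of the (unit-area) pseudo-Voigt lineshape kernel."""
    f = broadening.fwhm_mT
    half = max(int(np.ceil(12 * f / step_mT)), 3)
    half = min(half, (max_len - 1) // 2)
    x = np.arange(-half, half + 1) * step_mT
    ln2 = np.log(2.0)
    gauss = np.sqrt(4 * ln2 / np.pi) / f * np.exp(-4 * ln2 * x**2 / f**2)
    dgauss = gauss * (-8 * ln2 * x / f**2)
    denom = 1 + 4 * x**2 / f**2
    dlor = -(16 * x / (np.pi * f**3)) / denom**2
    gf = broadening.effective_gauss_fraction
    return gf * dgauss + (1 - gf) * dlor


def _orientation_weights(grid: OrientationGrid, dist: OrientationDistribution) -> np.ndarray:
    w = grid.weights * order_weight(grid.theta, dist.lambda_order)
    return w / w.sum()


def _stick_histogram(axis, positions, heights):
    """Accumulate stick spectra onto a uniform axis with linear splitting.

    Returns the histogram and the total weight that fell outside the axis.
    """
    step = axis[1] - axis[0]
    hist = np.zeros(axis.size)
    pos = (positions.ravel() - axis[0]) / step
    h = heights.ravel()
    inside = (pos >= 0) & (pos <= axis.size - 1)
    clipped = float(h[~inside].sum())
    pos, h = pos[inside], h[inside]
    i0 = np.minimum(pos.astype(int), axis.size - 2)
    frac = pos - i0
    np.add.at(hist, i0, h * (1 - frac))
    np.add.at(hist, i0 + 1, h * frac)
    return hist, clipped


def simulate_cw_spectrum(
    systems,
    dist: OrientationDistribution,
    grid: OrientationGrid,
    field_range,
    mw_frequency_GHz: float,
) -> CWSpectrum:
    """Simulate a first-derivative CW-EPR powder spectrum.

    ``systems`` may be a single SpinSystem or a list (weight-summed mixture);
    ``field_range`` is ``(min_mT, max_mT, npts)``.  Orientation-weighted stick
    intensities (quadrature weight x ordering weight, renormalized) are
    accumulated and convolved with each system's lineshape kernel; the
    returned intensity is the analytic first derivative with respect to field.
    Lines falling outside the field range raise a :class:`TruncationWarning`
    and mark the result ``truncated``.
    """
    if isinstance(systems, SpinSystem):
        systems = [systems]
    bmin, bmax, npts = field_range
    if not (bmax > bmin and npts >= 8):
        raise ValidationError("field_range must be (min, max, npts>=8) with max > min")
    axis = np.linspace(bmin, bmax, int(npts))
    step = axis[1] - axis[0]
    weights = _orientation_weights(grid, dist)
    total = np.zeros(axis.size)
    clipped_total = 0.0
    for system in systems:
        fields, intens = _system_resonances(system, grid.n_vecs, mw_frequency_GHz)
        hist, clipped = _stick_histogram(axis, fields, intens * weights[:, None])
        clipped_total += clipped
        kernel = _kernel_derivative(step, system.line_broadening, axis.size)
        total += system.weight * np.convolve(hist, kernel, mode="same") * step
    truncated = clipped_total > 1e-12
    if truncated:
        warnings.warn(
            f"resonance lines with total weight {clipped_total:.3g} fall outside "
            f"the field range [{bmin}, {bmax}] mT",
            TruncationWarning,
            stacklevel=2,
        )
    return CWSpectrum(axis, total, mw_frequency_GHz, truncated=truncated)


def frequency_rescale(spectrum: CWSpectrum, target_frequency_GHz: float) -> CWSpectrum:
    """Map a spectrum to a different microwave frequency (g-preserving).

    Each field point scales by target/actual so that the effective g value of
    every feature is unchanged; the intensity is untouched.
    """
    if not target_frequency_GHz > 0:
        raise ValidationError("target frequency must be positive")
    ratio = target_frequency_GHz / spectrum.mw_frequency_GHz
    return spectrum.replace(
        field_mT=spectrum.field_mT * ratio, mw_frequency_GHz=target_frequency_GHz
    )


# ------------------------------------------------------------------ g(omega)

def _system_frequencies(system, n_vecs, b0_mT):
    """Electron transition frequencies (GHz) and intensities at fixed field."""
    gmat = system.g.matrix()
    c = n_vecs @ gmat
    geff = np.linalg.norm(c, axis=1)
    nu_free = MU_B_MHZ_PER_MT * geff * b0_mT  # MHz
    n = n_vecs.shape[0]
    if not system.couplings:
        return nu_free[:, None] / 1e3, np.full((n, 1), 0.5)
    freqs = nu_free[:, None]
    intens = np.ones((n, 1))
    for coupling in system.couplings:
        s_ops, i_ops, hf, dim = _pair_block_operators(system, coupling)
        unit, _ = _zeeman_units(system, n_vecs, s_ops, i_ops, coupling.gamma_MHz_per_mT)
        h = b0_mT * unit + hf
        w, v = np.linalg.eigh(h)
        op1, op2 = _perpendicular_ops(n_vecs, s_ops)
        gaps = np.empty((n, dim * dim))
        amp = np.empty((n, dim * dim))
        for p, (lo, hi) in enumerate((i, dim + f) for i in range(dim) for f in range(dim)):
            gaps[:, p] = w[:, hi] - w[:, lo]
            m1 = np.einsum("nd,nde,ne->n", v[:, :, hi].conj(), op1, v[:, :, lo])
            m2 = np.einsum("nd,nde,ne->n", v[:, :, hi].conj(), op2, v[:, :, lo])
            amp[:, p] = (np.abs(m1) ** 2 + np.abs(m2) ** 2) / 2.0
        shift = gaps - nu_free[:, None]
        freqs = (freqs[:, :, None] + shift[:, None, :]).reshape(n, -1)
        intens = (intens[:, :, None] * amp[:, None, :]).reshape(n, -1)
    return freqs / 1e3, intens


def spectral_density(
    systems,
    dist: OrientationDistribution,
    grid: OrientationGrid,
    b0_T: float,
    kernel_fwhm_GHz: float = 0.05,
    npts: int = 2001,
    freq_axis_GHz: Optional[np.ndarray] = None,
) -> SpectralDensity:
    """Electron spectral density g(omega) at static field ``b0_T``.

    Transition frequencies nu(theta, phi, nuclear projections) are accumulated
    with orientation and ordering weights, smoothed with a Gaussian kernel of
    FWHM ``kernel_fwhm_GHz``, and normalized to unit integral.  ``width_d`` is
    reported as twice the square root of the second central moment -- the
    effective line width D that shrinks as g anisotropy (proportional to B0)
    or hyperfine spread (field-independent) shrinks.
    """
    if not b0_T > 0:
        raise ValidationError("b0 must be positive")
    if isinstance(systems, SpinSystem):
        systems = [systems]
    b0_mT = b0_T * 1e3
    weights = _orientation_weights(grid, dist)
    all_freqs, all_heights = [], []
    for system in systems:
        freqs, intens = _system_frequencies(system, grid.n_vecs, b0_mT)
        all_freqs.append(freqs.ravel())
        all_heights.append((system.weight * intens * weights[:, None]).ravel())
    freqs = np.concatenate(all_freqs)
    heights = np.concatenate(all_heights)
    if freq_axis_GHz is None:
        pad = 6 * kernel_fwhm_GHz
        freq_axis_GHz = np.linspace(freqs.min() - pad, freqs.max() + pad, int(npts))
    axis = np.asarray(freq_axis_GHz, dtype=float)
    step = axis[1] - axis[0]
    hist, _ = _stick_histogram(axis, freqs, heights)
    sigma = kernel_fwhm_GHz / (2 * np.sqrt(2 * np.log(2)))
    half = max(int(np.ceil(6 * sigma / step)), 1)
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    density = np.convolve(hist, kernel, mode="same")
    density = np.clip(density, 0.0, None)
    density /= np.trapezoid(density, axis)
    mean = np.trapezoid(axis * density, axis)
    var = np.trapezoid((axis - mean) ** 2 * density, axis)
    return SpectralDensity(axis, density, b0_T, width_d_GHz=2.0 * np.sqrt(var))


def compose_components(components) -> SpectralDensity:
    """Weighted, re-normalized sum of spectral densities on a common axis.

    ``components`` is a list of ``(weight, SpectralDensity)``; all must share
    the same static field.  Used to superpose differently ordered
    subpopulations (different lambda) into one effective g(omega).
    """
    if not components:
        raise ValidationError("need at least one component")
    weights = np.array([w for w, _ in components], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValidationError("weights must be nonnegative and not all zero")
    b0 = components[0][1].b0_T
    for _, comp in components:
        if abs(comp.b0_T - b0) > 1e-12:
            raise ValidationError("all components must share the same b0")
    lo = min(c.freq_axis_GHz[0] for _, c in components)
    hi = max(c.freq_axis_GHz[-1] for _, c in components)
    npts = max(c.freq_axis_GHz.size for _, c in components)
    axis = np.linspace(lo, hi, npts)
    density = np.zeros(npts)
    for w, comp in components:
        density += w * np.interp(axis, comp.freq_axis_GHz, comp.density, left=0.0, right=0.0)
    density /= np.trapezoid(density, axis)
    mean = np.trapezoid(axis * density, axis)
    var = np.trapezoid((axis - mean) ** 2 * density, axis)
    return SpectralDensity(axis, density, b0, width_d_GHz=2.0 * np.sqrt(var))


# ------------------------------------------------------------------ presets

def carbon13_sar1(fwhm_mT: float = 0.8, g_iso: float = 2.003698) -> SpinSystem:
    """The dominant stable radical R1 of electron-irradiated [1-13C]alanine.

    Experimentally determined hyperfine tensor to the carboxyl 13C: principal
    values [-1.80266, -15.8427, 64.6933] MHz with z-y-z Euler angles
    [1.50914, 1.30749, 0.761318] rad in the standard molecular frame of the
    alanine radical; the g tensor is taken isotropic at the measured mean
    value.
    """
    return SpinSystem(
        g=TensorSpec([g_iso, g_iso, g_iso]),
        couplings=[
            NucleusCoupling(
                "13C",
                0.5,
                TensorSpec([-1.80266, -15.8427, 64.6933], [1.50914, 1.30749, 0.761318]),
            )
        ],
        line_broadening=LineBroadening(fwhm_mT=fwhm_mT),
    )
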