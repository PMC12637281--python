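# Methods

This note documents the models implemented in `spinpol`, the conventions
and defaults they use, and what the synthetic-data generators do and do
not emulate. Units throughout: magnetic field in mT (static fields for
DNP contexts in T), frequencies in GHz (hyperfine couplings in MHz),
times in s unless stated, chemical shift in ppm.

## Spin-Hamiltonian simulation

An S=1/2 electron couples to a set of nuclei through anisotropic
hyperfine tensors A (MHz) and to the field through an anisotropic g
tensor. For an orientation **n** of B₀ in the molecular frame the
working Hamiltonian per electron–nucleus pair, in frequency units, is

    H/h = (μ_B/h) B nᵀg·S + S·A·I − γ_n B n·I ,

with μ_B/h ≈ 13.996 MHz/mT and γ_n the nuclear gyromagnetic ratio
(γ(¹³C)/2π = 10.7084 MHz/T, fixed). Tensors are specified by three
principal values and active z-y-z Euler angles rotating the tensor frame
into the molecular frame.

**Line positions.** Each electron–nucleus pair block (dimension
2(2I+1)) is diagonalized exactly; resonance fields solve
ΔE(B) = hν by Newton iteration with the Zeeman-dominated slope
μ_B g_eff/h, four iterations from the free-electron field (residuals
converge to <10⁻⁶ mT because ΔE is nearly linear in B over the few-mT
correction). Transition intensities are |⟨f|S_⊥|i⟩|² averaged over two
perpendicular microwave axes, which retains the weak "forbidden" lines
produced by nuclear state mixing. Multiple nuclei combine additively
(independent-nucleus approximation): per-nucleus field shifts relative
to the free-electron line are summed over all projection combinations
and intensities multiplied. The test suite checks this against an
independent brute-force oracle — full tensor-product diagonalization
with dense field scanning and Brent root refinement — to <0.01 mT for
the single-¹³C radical and <0.02 mT with an added proton (the neglected
inter-nucleus cross terms scale as δ₁δ₂/B ≈ µT at X-band).

**Powder averaging and partial order.** Orientations come from a
deterministic golden-spiral equal-area grid over the hemisphere
(default 10,000 points; no RNG in the simulator). Partial molecular
ordering is the axial distribution p(α) = exp[−λ(3cos²α−1)/2] of the
molecular z axis against B₀: λ=0 is an isotropic powder, λ>0
concentrates density toward α=π/2, λ<0 toward the pole; weights are
renormalized after reweighting, so g(ω) stays a unit-integral density
for any λ.

**Lineshape.** Stick spectra are accumulated onto the field axis with
linear bin splitting and convolved with the analytic *derivative* of a
pseudo-Voigt kernel (configurable Gaussian fraction, default 0.5; FWHM
default 0.8 mT — no linewidth is published for these radicals, so this
is a package default chosen to resemble the visibly broadened SAR
spectra). The kernel is truncated at ±12 FWHM (capped at the axis
length). Simulated intensity is therefore the first derivative of the
absorption and integrates to ~0; lines falling outside the requested
field range raise a `TruncationWarning` and mark the spectrum.

**Default radical.** `carbon13_sar1()` builds the dominant stable
alanine radical R1 of [1-¹³C]alanine with the experimentally determined
¹³C hyperfine tensor [−1.80266, −15.8427, 64.6933] MHz, Euler angles
[1.50914, 1.30749, 0.761318] rad, and an isotropic g of 2.003698 (only
the mean g is published; anisotropic g is supported but not defaulted).
The machinery accepts weighted multi-species mixtures; the default is
the single dominant species.

**Spectral density.** g(ω) at fixed B₀ accumulates the exact pair-block
transition frequencies with the same orientation/order weights, smooths
with a Gaussian kernel (default FWHM 0.05 GHz) and normalizes to unit
integral (enforced to 10⁻⁶). The effective width D is reported as twice
the root second central moment; with hyperfine couplings removed it
scales proportionally to B₀ (g anisotropy), while hyperfine
contributions are field-independent. `compose_components` superposes
densities from subpopulations with different λ on a common axis and
renormalizes — the mechanism for representing a texture-ordered sample
as a mixture of ordering states.

## Tensor fitting

The objective is 1 − ⟨model, data⟩ after scaling both spectra to unit
L2 norm (cosine distance): CW amplitudes are instrument-scaled, so the
objective must be amplitude-invariant; it is 0 iff the spectra are
proportional and 2 for a sign flip. Minimization is differential
evolution (Sobol initialization, seeded, polish disabled, the initial
system injected as x0) under finite box bounds; the budget caps
simulator calls. Convergence is declared when the best objective
improves by <10⁻⁴ relative over the last 20 % of the budget. Tensor
sign/permutation degeneracies are removed from reports by sorting
principal values by |value| and folding Euler angles into [0, π).
Uncertainty is reported only as each parameter's position within its
bounds — no posterior is computed.

## Spin counting

The spin count is proportional to the double integral of the
baseline-corrected first-derivative spectrum: cumulative trapezoid
(→ absorption), then trapezoid. Baseline is a polynomial (default
order 1) fitted only on the outer margins (default 10 % each side),
which the caller must keep signal-free. Instrument normalization
divides by Q, receiver gain, modulation amplitude, √(microwave power)
and sample mass; absent factors are skipped with a logged notice
(the full factor list used by any given spectrometer script varies, so
the set is configurable). Concentration calibration is least squares
through the origin against standards (zero concentration must give
zero signal); negative standard integrals are accepted but flagged.
The dose response uses the saturating exponential
N(D) = N∞(1 − e^(−D/D_c)) — the standard two-parameter form for
radical accumulation approaching saturation (~70 kGy for these
samples); decreasing count-vs-dose data are flagged as poorly
specified rather than fitted with a negative D_c. Storage stability is
an OLS slope with a two-sided t confidence interval (α = 0.05);
"stable" means the CI contains zero.

## DNP mechanism models

All sweep models consume a normalized g(ω) and a context holding B₀,
the lattice temperature T_L and the nuclear Larmor frequency
ω_N/2π = γ(¹³C)B₀.

- **Solid effect**: E(ω_mw) = g(ω_mw+ω_N) − g(ω_mw−ω_N), normalized to
  unit max; positive lobe below the line (ω̄_e − ω_N). This is the
  delta-line limit of the differential solid effect and places extrema
  at ω̄_e ∓ ω_N for a narrow line.
- **Thermal mixing** (Borghini-type stationary model): the non-Zeeman
  reservoir takes an inverse spin temperature β solving
  ∫ g(ω)(ω−ω_mw)[P_L(ω) − tanh(u(ω−ω_mw)sβ)] dω = 0, with
  P_L(ω) = tanh(uω/T_L), u = h/2k_B in K/GHz, and s a dimensionless
  electron–nuclear coupling scale (default 1; it is not derivable from
  desk-side inputs and is exposed as a parameter). The balance is
  strictly decreasing in β, so the bracketed Brent solve is
  deterministic with a unique root; an empty bracket returns the zero
  solution, flagged. Predicted nuclear polarization is tanh(uω_N sβ).
  For any unimodal symmetric g this yields the classic bimodal profile
  with one zero at the barycenter. (The zero is exact only in the
  constant-P_L limit; the slow variation of P_L across the line leaves
  a ~10⁻⁵ residual, which the tests account for.)
- **Cross effect**: the heuristic shape g(ω)[g(ω−ω_N) − g(ω+ω_N)],
  included only to show that this model family shares the bimodal
  signature.
- **Swept irradiation**: a centered moving average of the
  fixed-frequency profile over the sweep width — a first-order model of
  frequency-modulated microwaves addressing a band of the line.

None of these reproduces the experimentally observed *unimodal*
high-field sweep profile of dense irradiated samples; that is a known
open problem, and the package deliberately stops at the models the
observation is contrasted against.

**Buildup kinetics** follow y = P[A(1−e^(−t/T)) + (1−A)(1−e^(−t/τ))]
with 0 ≤ A ≤ 1 and T < τ enforced (branch swap after fitting).
Biexponential fits use bounded least squares from five seeded starts;
`model="auto"` compares mono (k=2) and bi (k=4) by small-sample
corrected AIC. T is reported in seconds and τ in hours, matching the
units the dose-series parameters are quoted in. Fits with τ/T < 3 are
flagged weakly identified.

## Polarimetry

Repeated small-angle readout of a hyperpolarized liquid gives
s_n = S₀ sinθ cosθ^(n−1) e^(−(n−1)TR/T₁): each pulse consumes
1−cosθ of the magnetization, so the raw envelope decays faster than
T₁ by ln cosθ per TR. The fit initializes from the log-linear envelope
slope and refines with bounded least squares; the apparent decay time
is also reported for comparison. Back-extrapolation to dissolution is
P₀ = P_measured·e^(+elapsed/T₁) — the delay is treated as pure T₁
decay, with transfer losses excluded by convention. Thermal
polarization is the two-level closed form tanh(hν/2k_BT); the sample
temperature for the thermal reference defaults to 300 K (not printed
with the published enhancement; 300 K reproduces ε ≈ 142,000 from
P = 17 % at 1.4 T within 0.2 %). Benchtop readout defaults used by the
generators (flip 5°, TR 5 s, 60 points) are declared synthetic
conventions, not measured settings.

## MRS quantification and redox

Frames are fitted in the frequency domain as sums of phased Lorentzians
with box priors: shift within ±2 ppm of the prior, amplitude ≥ 0,
half-width within 5× of the prior, phase within ±0.5 rad (fixed at 0 by
default). This is a simplified frequency-domain analogue of time-domain
prior-knowledge (AMARES-style) fitting; the pipeline consumes relative
amplitudes and shifts, which this surface recovers with fewer
conventions (no truncated-FID handling, no first-order phase).
Time series are fitted per frame with warm-started priors, or in
"summed" mode the frame sum is fitted once to trade temporal resolution
for SNR. Failed frames produce NaN amplitudes. Fits where all
amplitudes sit at the noise floor (5× the MAD of the residual) are
flagged empty; fits where two shifts converge within one half-width are
flagged collapsed.

Defaults place lactate at 183 ppm and pyruvate at 171 ppm (literature
[1-¹³C] values); **alanine's 176.6 ppm is a package convention**, chosen
only to sit between them, and must not be read as a measured value.

NAD⁺/NADH derives from the lactate-dehydrogenase equilibrium
K_eq = [pyr][NADH][H⁺]/([lac][NAD⁺]) = 1.11×10⁻¹¹ M:
NAD⁺/NADH = (pyr/lac)·10^(−pH)/K_eq. Peak amplitudes stand in for
concentrations — both resonances are C1 carbons of three-carbon acids,
so the proportionality cancels in the ratio; no per-metabolite T₁ or
flip-angle correction is applied. pH is an external input (e.g. from
³¹P-MRS); no pH estimation is implemented.

## Synthetic data

Every generator is a pure function of (parameters, seed) returning the
dataset plus a ground-truth sidecar dict. Noise is additive Gaussian
with σ expressed as a fraction of max|signal| (multiplicative optional);
"0.5 % noise" in the recovery protocols means σ = 0.005×signal scale.

The MRS generator renders a three-pool unidirectional cascade
ala → pyr → lac: constant rate matrix with per-pool T₁, exact matrix
exponential between pulses (augmented-matrix form for the constant
bolus influx), cosθ depletion of all pools at each pulse, sinθ readout.
Defaults: k(ala→pyr) = 0.1 s⁻¹, k(pyr→lac) = 0.2 s⁻¹,
T₁ = (45, 25, 33) s, 10 s bolus, 30° flip, TR 3 s, 100 frames, 2048
points over 160–195 ppm. No rate constants are published for this
experiment; these values were chosen once so that the downstream pools
are clearly visible above an SNR-50 noise floor with lactate exceeding
pyruvate, qualitatively matching the in vivo spectra. The cascade has
no back-reaction and no perfusion/compartment structure, so passing
round-trip tests demonstrates quantification fidelity, not biological
realism: real in vivo data add B₀ drift, lineshape distortion,
baseline from residual water/lipid and partial-volume effects that the
generator does not emulate.

The EPR generator wraps the simulator plus noise; the buildup, decay,
calibration and dose generators sample their closed-form models
directly. What passing recovery tests shows is that the estimators are
correct and well-conditioned under the stated noise; instrument
artifacts (baseline drift beyond polynomial order, saturation,
modulation broadening) are out of scope.

## Problem sizes and numerical settings

Tests and the acceptance script run at desk scale: powder grids of
256–3,000 orientations (50 for the oracle comparison, 20,000 for the
Monte-Carlo histogram check against 10⁶ random orientations), field
axes of 256–2,048 points, buildup curves of ~1,400–2,900 samples,
60-point decays, 40-frame MRS series. Tensor-fit recovery uses a
256-orientation grid and a 2,000-evaluation budget. The thermal-mixing
solver brackets β in ±10⁴/T_L K⁻¹ with Brent tolerances 10⁻¹²
(absolute) and 10⁻¹⁴ (relative).

## Known limitations

- Independent-nucleus line combination: exact per nucleus, additive
  across nuclei; fine below ~100 MHz couplings at X-band, untested for
  strongly coupled multi-nucleus systems far off this regime.
- The 5 K spectrum of glycerol-mixed samples (altered g and hyperfine
  structure) is not modeled — the room-temperature radical model does
  not extend to it.
- No pulsed-EPR observables, no relaxation-time prediction, no
  electron–electron dipolar couplings, no time-domain simulation of the
  swept-microwave sequence.
- Spin counting is relative: absolute counts require a calibration
  standard; no cavity/transition-moment first-principles calibration.
- MRS fitting assumes Lorentzian lines on an ideal baseline; no MRSI
  spatial reconstruction, no kinetic rate-constant (k_PL-style) fits.
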