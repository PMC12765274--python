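# Methods

This note records the models, conventions, parameter choices and
limitations behind `chirpsifter`, in the spirit of a simulation package's
methods documentation. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pulse model

A chirp pulse is the complex envelope `S(t) = ω₁(t)·exp(iφ(t))` in the
rotating frame, on the symmetric coordinate `t ∈ [−tp/2, +tp/2]`. The
amplitude is the WURST profile `ω₁(t) = ω₁ᵐᵃˣ·(1 − |sin(πt/tp)|ⁿ)`; the
instantaneous frequency sweeps linearly over SW, giving the quadratic
phase `φ(t) = s·π·(SW/tp)·t² (+ 2π·f_offset·t)`, with phase zero at the
pulse center. A closed form is used for the phase; the sampled waveform is
checked against it to 1e−9 rad in the tests.

Units: public interfaces use nanoseconds and megahertz; the waveform
samples and Bloch fields are rad/s. The critical adiabaticity
`Q = ω₁²·tp/(2π·SW)` mixes angular (ω₁) and linear (SW) frequency — the
classic 2π pitfall — so a dedicated test pins Q(18.7 MHz, 100 ns,
500 MHz) ≈ 0.44.

Sampling: default spacing `min(tp/1000, 1/(16·(SW + ν₁/2 + |f_off|)))` —
at least 1000 samples per pulse and 16 per period of the fastest
oscillation. An explicit `dt` that would allow more than π/8 phase advance
per step at the band edge is rejected, and the propagator independently
rejects per-step rotations above π/4.

Resonator pre-compensation divides each sample's amplitude by the
normalized nutation response at that sample's instantaneous frequency,
then rescales to the original peak. It is amplitude-only: the frequency
sweep is not warped (sweep warping is a possible extension, deliberately
not a default), and a response floor of 0.05 guards against unbounded
boosts in resonator notches.

## Refocusing-ratio solver

For chirp pulses sharing one sweep width, a coherence pathway refocuses
the excitation phase roll when `Σᵢ sᵢ·tpᵢ·(o⁻ᵢ − o⁺ᵢ) = 0`. Several
pathways, fixed lengths, length equalities, and two pseudo-pathway
constraints (dispersion matching of a two-pulse echo onto a later π/2
pulse; the solid-echo 2:1 condition between the two π/2 pulses) assemble
into a homogeneous rational linear system, solved exactly (sympy rational
Gauss–Jordan; lengths are `fractions.Fraction`). Feasible solutions are
the strictly positive rays of the nullspace; residuals of returned
solutions are exactly zero.

Normalization and ranking: lengths are reported with the shortest π-role
pulse scaled to 1, because the shortest π pulse sets the minimal absolute
pulse lengths at a given amplifier limit; sweep-pattern enumeration ranks
by the total length under that scaling, breaking ties by the longest
single pulse, then up-sweeps first.

Under-determined families: many constraint sets leave one or more free
parameters (e.g. the up–down–up–down solid-echo system, whose general
solution is `(2a, b, a, a+b)`). The solver then reports the smallest
primitive positive-integer member, preferring members in which **every
π-role pulse is strictly longer than every π/2-role pulse** — π pulses
need a much higher nutation amplitude (Q ≈ 5 versus 0.44), so at a fixed
amplifier ceiling they should carry the longer relative lengths. Under
this rule the family above yields 2:3:1:4. The preference is a soft
ranking criterion, not a filter: unique solutions are returned as-is even
when they violate it (e.g. 2:2:2:1, whose last π pulse is short). The
full family remains accessible through the enumeration API and CLI.

Echo-time prediction for multiple pathways uses interval bookkeeping over
center-to-center delays, `t_echo = −(Σⱼ oⱼ·dⱼ)/o_det`; the 2:2:6:3
up–down–down–down sequence refocuses both SIFTER pathways (both residuals
zero) at times separated by `2(d₂ − d₁)`.

## Sequence timing

All delays are **center-to-center**. For linear chirps this makes the
refocusing arithmetic exact (an on-center spin is acted on exactly at the
pulse center); edge-to-edge is the more common bench convention, so
configurations must be converted before comparison with spectrometer
settings. Pulse amplitudes are set per role: π/2 pulses exactly at
Q = 2ln2/π, all π pulses at one shared configurable Q (default 5), which
for 2:1 lengths reproduces the 1:√2 amplitude relation and lets equal-Q π
pairs compensate their dynamic phases.

Sweep directions not uniquely fixed by the design (the 2:2:2:1 and
six-pulse templates) default to all-up and are configurable.

2D schedules expose `dt` as the **dipolar-axis increment per point**: the
four-pulse rule is τ₁ −= dt/2, τ₂ += dt/2; the six-pulse rule is
τ₁ −= dt/2 with τ₂, τ₃, τ₄ each += dt/6 (the same 3:1 split as the
per-delay description of the experiment, expressed per axis unit). Pulse
lengths never change during a schedule, so the refocusing residuals stay
zero at every point; feasibility (no pulse overlap at any point) is
checked and the maximal feasible point count reported on failure.

The diagnostic 2:2:2 refocused echo deliberately does *not* satisfy the
refocusing condition (residual −2): its purpose is the equal-TBP π-pulse
pair, which flattens φ₀(Q) while leaving the parabolic offset phase in
place. It therefore declares no refocusing pathway.

## Bloch simulation

Spins are independent S = 1/2 vectors without relaxation. Each waveform
interval applies an exact axis-angle rotation about
`(scale·ω₁cosφ, scale·ω₁sinφ, Ω)`; free evolution is an analytic
z-rotation. Norm is conserved to < 1e−10 over full sequences; the
propagator is cross-checked against direct ODE integration of
`dM/dt = ω × M` to 1e−6 on the same piecewise-constant field.

Rotation sense: magnetization rotates right-handedly about the field, so a
rectangular (π/2)x takes +z to −y, and the rectangular x,x Hahn echo forms
along +y (φ₀ = +π/2) — the standard statement of the echo phase. M_xy is
Mx + i·My; free evolution multiplies it by `exp(+iΩt)`.

Default ensemble: 1000 spins uniform over ±100 MHz. A uniform offset grid
makes the discrete transient periodic with period 1/Δν; the default
detection window is clamped below 0.8 of that period so the echo cannot
alias to a spurious time (this, not physics, is why small uniform
ensembles need narrow windows).

B1 inhomogeneity is a half-Gaussian distribution of relative amplitudes:
21 scales on `[1 − 4σ, 1]`, weights ∝ exp(−(1−s)²/2σ²) normalized to one.
Most of a resonator's sample sits at full field; only the edges see less —
hence the one-sided shape. The truncation at 4σ and the 21-point grid are
package choices. σ = 0.05 is the reference width used in the amplitude
studies. The B1-averaged transient is exactly the weighted sum of
per-scale transients (tested).

Echo observables: the echo time is the |transient| maximum with 3-point
parabolic refinement (the fidelity is the refined peak value); the
per-offset phases are referenced to the phase-stationary time, polished
from the amplitude maximum by removing the residual linear phase slope
over the central 60 % of the band (without this, a fraction-of-a-sample
timing error would masquerade as a linear Δφ ramp). φ₀ is read from the
spin nearest Ω = 0, Δφ(Ω) from the unwrapped per-offset phases after
subtracting φ₀ only (zero-order correction), and the parabolic roll from a
quadratic fit over the central 60 %. φ₀(Q) slopes are fitted on
Q ∈ [4, 10], above the low-Q region of incomplete coherence inversion.

Observed phenomenology (all asserted by tests, none hard-coded): φ₀ is
near-linear in Q with a slope set by the TBP alone (equal-TBP
configurations agree to well under 5 %); the 2:2:2 sequence's slope is
below 0.02 rad/Q; ABSTRUSE retains a small nonzero slope (its π pulses
have unequal TBP) while refocusing Δφ to < 5° over the central 60 % of the
±100 MHz ensemble at Q = 10; under σ = 0.05 B1 spread the echo-versus-Q
curve has an interior maximum followed by a monotone decline, shorter
pulses and even π-pulse counts give higher maxima, and more π pulses shift
the maximum to higher Q.

### SIFTER calibration and the 2:3:1:4 amplitude

The SIFTER echo oscillates with the joint π-pulse amplitude because the
first-echo phase at the (π/2)y pulse must be an odd multiple of π/2;
maxima/minima of the simulated amplitude sweep coincide with
half-integer/integer multiples of π of that phase (verified on ≥ 10
consecutive extrema to better than π/6 after parabolic refinement of the
extremum positions).

The 2:3:1:4 sequence transmits only the component of the dispersed first
echo that arrives along y at the (π/2)y pulse. Its simulated amplitude
versus Q oscillates about a plateau at half the 2:2:2:1 amplitude; the
oscillation (±0.04 here) is a stationary-phase contribution from offsets
near Ω = 0 whose phase scans with Q. The package quotes the sequence's
amplitude as the plateau mean over at least two oscillation periods
(Q ∈ [6, 12]); the 2:2:2:1 reference, whose curve is smooth and unimodal,
is quoted at its maximum (Q ∈ [3, 6]). The measured ratio is ≈ 0.52.

## Dipolar simulation

A rigid two-spin model: conformers of (r, Euler angles of each label's
tensor frame relative to the inter-spin frame, weight). Offsets use the
first-order resonance expression with effective
`g(n) = √(Σ gᵢ²nᵢ²)` and `A(n)` likewise, three equally weighted ¹⁴N m_I
manifolds, default tensors g = (2.0086, 2.0066, 2.0026),
A = (14, 14, 95) MHz (typical literature nitroxide values, not fitted to
any specific sample) at a 9.6 GHz reference. The dipolar constant
D = 52.04 MHz·nm³ is a configurable module constant; exchange coupling is
fixed at zero.

The powder average uses a deterministic golden-spiral grid (default 2000
orientations, equal weights); seeds never affect quadrature, only noise.
Each orientation contributes `(1−λ) + λ·cos(2πν_dd t)` per label into that
label's offset bin, so the t = 0 column is the absorption spectrum and the
offset-summed signal equals the 1D form factor on the same quadrature
exactly. Unresolved proton hyperfine broadening is modeled as a Gaussian
convolution over offset bins (default FWHM 8 MHz — the mechanism is
standard, the width a package default). Bin margins are sized so the
convolution loses no spectral mass.

The synthetic dataset wraps the ideal signal with: a Gaussian-shaped
refocusing envelope `exp(−(t/T_env)²)` peaking at the τ₁ = τ₂ point
(default T_env = 6 µs), an exponential intermolecular background
`exp(−k|t|)` (default k = 0.1 µs⁻¹), modulation depth λ (default 0.5), an
optional per-offset sensitivity profile, and seeded white Gaussian noise
(default σ = 1 % of the spectrum maximum). The SIDRE companion trace
carries the envelope only (plus independent noise), so the pipeline's
exponential-background fit remains a genuine correction step. The
functional form of the SIFTER background is an open question
experimentally; this generator is a declared emulation, not a claimed
faithful background model. Datasets are byte-identical under a fixed seed.

What the generator does *not* emulate: orientation-dependent relaxation,
partial dipolar refocusing inside the chirp pulses, multi-spin
contributions, nuclear modulation (ESEEM), and receiver artifacts — so
passing round-trip tests demonstrates the correctness of the processing
chain, not robustness to every feature of measured data.

## Processing

Echo FT: FFT of the transient with the echo center shifted to time zero
(shift theorem) and zero-order phase chosen to maximize the integrated
real part (the phasing criterion is a package choice). Echoes centered
within 10 % of the record edge are rejected as truncated.

Excitation-profile post-correction: field-stepped spectra move the
spectrum across the fixed excitation/detection sensitivity; following one
spectral point across ≥ 5 steps traces the profile, and dividing the echo
FT by it restores the true spectral shape (round trips recover imposed
profiles to ~1 % RMS).

Background correction divides by the SIDRE trace, then by a log-linear
exponential fit on the last 60 % of the dipolar axis (window
configurable); log-linear is chosen over nonlinear least squares for
robustness. The 2D dipolar transform background-corrects each offset
column, normalizes it, re-weights by its pre-correction t = 0 intensity,
and applies a magnitude FFT without zero filling or apodization; columns
whose t = 0 intensity is below 5 % of the strongest column are excluded
(edge-of-spectrum columns cannot support a reliable exponential fit).
Both signed and folded frequency axes are derivable; the folded axis is
reported, and a heatmap mode squares each normalized column.

Tikhonov inversion solves `min ‖Kp + c − F‖² + α²‖L₂p‖²` with p ≥ 0 by
NNLS on the stacked system, where K is the powder dipolar kernel
`K(t,r) = ∫₀¹ cos[2π(D/r³)(1−3x²)t] dx` (Gauss–Legendre, 401 nodes,
cross-checked against a brute-force Riemann sum to 1e−6), L₂ the second
difference, and c a free constant absorbing the unmodulated fraction.
α defaults to the L-curve maximum-curvature corner over a log grid
(1e−4…10, 24 points); GCV is available. In the α → ∞ limit the
second-difference penalty drives the curvature to zero (an affine, not
constant, profile). Degenerate all-zero fits raise with diagnostics.
Distributions are normalized to unit integral.

## Problem sizes

Simulation studies in the tests use 81–301 spins (against the 1000-spin
default) with offset grids chosen so the alias period comfortably exceeds
the detection window, 600–2000 powder orientations, 192–256-point dipolar
axes at 16 ns, and 7–61-point Q grids; these sizes reproduce the
phenomenology listed above with margin. The round-trip study runs ten
noise seeds at σ = 0.5 % noise and recovers the 3.5 nm input distance
within one 0.05 nm grid step each time.

## Known limitations

* No relaxation, instantaneous diffusion, or ESEEM; the Bloch model
  cannot reproduce echo-amplitude differences that stem from T₂ during
  the long chirps.
* Coherence-pathway amplitudes *within* chirp pulses (operator-level
  partial refocusing) are outside the vector model; the 2:3:1:4 and
  six-pulse variants would need an operator treatment for quantitative
  short-distance work.
* The transfer-function correction is amplitude-only.
* Offsets enter at first order (effective g/A); no nuclear-quadrupole or
  second-order hyperfine shifts.
* The SIFTER background model is an emulation (see above); measured
  backgrounds may differ systematically.
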