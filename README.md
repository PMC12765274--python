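# chirpsifter

A shaped-pulse toolkit for broadband pulsed dipolar EPR spectroscopy, built
around the two-dimensional, EPR-correlated SIFTER experiment (the
single-frequency technique for refocusing) with WURST chirp pulses.

Pulsed dipolar spectroscopy measures nanometer distances between two spin
labels on a biomolecule through their dipolar coupling. SIFTER excites and
refocuses the *whole* nitroxide spectrum at a single carrier frequency,
which at X band requires frequency-swept (chirp) pulses. Chirps tip spins
at different offsets at different times, so sequence design becomes a
timing problem: pulse-length ratios and sweep directions must refocus the
resulting phase roll, and the residual "dynamic" (Bloch–Siegert-type)
phases control the echo phase and — under B1 inhomogeneity — the echo
amplitude. This package implements that design and analysis chain for
people setting up or simulating broadband SIFTER-type experiments:

* **`pulse_shapes`** — WURST chirp construction and sampling, critical
  adiabaticity Q, time-bandwidth product, flip angles, and amplitude-only
  resonator transfer-function pre-compensation.
* **`ratio_solver`** — exact (rational-arithmetic) solver for the linear
  refocusing condition `sum_i s_i · tp_i · (o⁻_i − o⁺_i) = 0` over
  arbitrary coherence pathways, sweep-direction enumeration, and
  dual-pathway echo-time prediction.
* **`sequences`** — named templates (2:1 Hahn, 2:2:1 ABSTRUSE, 2:2:2:1 /
  2:2:6:3 / 2:3:1:4 SIFTER, 2:2:2:2:3:2 six-pulse SIFTER, SIDRE
  references) with center-to-center timing and 2D dipolar schedules.
* **`bloch_sim`** — ensemble Bloch-vector simulation (axis-angle
  propagation, no relaxation) with half-Gaussian B1 averaging; extracts
  the echo transient, fidelity, the offset-independent echo phase φ₀, the
  offset-dependent Δφ(Ω), and the parabolic phase roll.
* **`dipolar_sifter`** — orientation-selective 2D-SIFTER/SIDRE simulation
  for rigid nitroxide pairs (g/A tensors, golden-spiral powder average)
  and a seeded synthetic-dataset generator (envelope, exponential
  background, modulation depth, noise).
* **`processing_2d`** — echo FT with phasing, excitation-profile
  post-correction from field-stepped spectra, SIDRE + exponential
  background division, 2D magnitude FT, and non-negative Tikhonov
  inversion to a distance distribution.

## Core quantities

A WURST pulse is `S(t) = ω₁(t)·exp(iφ(t))` on `t ∈ [−tp/2, +tp/2]` with
`ω₁(t) = ω₁ᵐᵃˣ (1 − |sin(πt/tp)|ⁿ)` and a linear frequency sweep of width
SW, so `φ(t) = s·π·(SW/tp)·t²`. Its effective flip angle follows from the
critical adiabaticity

```
Q = ω₁²·tp / (2π·SW),        β = arccos(2·e^(−πQ/2) − 1),
```

so an exact π/2 flip needs `Q = 2·ln2/π ≈ 0.44`, while π pulses approach
β = π asymptotically (Q ≈ 5 is ample). The dipolar frequency of a rigid
pair at distance r (nm) and orientation θ is
`ν(θ) = (52.04 MHz·nm³ / r³)·(1 − 3cos²θ)`.

## Worked example

Solve the refocused-echo pulse-length ratios over all sweep directions
(first two pulses equal, π/2–π–π roles):

```
$ chirpsifter solve-ratios --pulses 3 --pathway "0,1;1,-1;-1,1" \
      --equal 0,1 --roles "pi/2,pi,pi"
udd   2:2:3   3.5   unique
duu   2:2:3   3.5   unique
uuu   2:2:1   5     unique
ddd   2:2:1   5     unique
```

Each row is a sweep pattern (u = up, d = down), its exact integer
length ratio, the total length with the shortest π pulse scaled to 1 (the
ranking metric — shorter is better), and whether the solution is unique.
The all-up 2:2:1 solution is the classic ABSTRUSE refocused echo.

Simulate a four-pulse 2:2:2:1 SIFTER echo (100 ns unit, 500 MHz sweep,
π pulses at Q = 4.5, 201 spins over ±100 MHz):

```
$ chirpsifter simulate-echo --template sifter_2221 --qcrit 4.5 --spins 201
{
 "echo_time_ns": 400.1944732641091,
 "phi0_rad": 0.09776998525067442,
 "fidelity": 0.9546401450052617
}
```

The echo refocuses τ₂ = 400 ns after the last pulse with 95 % of the spins
phase-aligned; φ₀ is the residual echo phase at the sweep center.

From Python, the π/2 adiabaticity and the matching nutation amplitude for
a 100 ns / 500 MHz chirp:

```python
>>> from chirpsifter import qcrit_for_flip, amplitude_for_qcrit
>>> import numpy as np
>>> q = qcrit_for_flip(np.pi / 2); round(q, 4)
0.4413
>>> round(amplitude_for_qcrit(q, 100, 500), 2)   # MHz
18.74
```

A full synthetic 2D dataset and its distance distribution:

```
$ chirpsifter synth-dataset --r 3.5 --seed 4 --out ds.h5
$ chirpsifter process-2d --input ds.h5 --out dist.txt
{
 "peak_nm": 3.5,
 ...
}
```

## Scope

The simulations treat independent S = 1/2 spins without relaxation;
spectrometer hardware calibration (amplifier linearization, AWG
quantization, mixer artifacts), phase cycling schemes, and multi-spin
(> 2) systems are out of scope. See `docs/methods.md` for the model
assumptions, numerical choices, and limitations.
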