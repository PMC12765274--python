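"""Bloch-vector simulation of chirp-pulse echo sequences.

Ensembles of non-interacting S = 1/2 spins (no relaxation) are propagated
through pulse sequences by rotating each magnetization vector about the
instantaneous effective field ``(w1*cos(phi), w1*sin(phi), Omega)`` with an
exact axis-angle (Rodrigues) step per waveform sample; free evolution is an
analytic z-rotation.  B1 inhomogeneity is modeled by repeating the
simulation at scaled pulse amplitudes and summing the transverse
magnetization with the distribution weights.

Rotation-sense convention: magnetization rotates right-handedly about the
effective field, so a rectangular (pi/2)x pulse takes +z to -y and a
rectangular x,x Hahn echo refocuses along +y (echo phase +pi/2).  The
complex transient is ``M_xy = Mx + i*My``.

The echo observables follow the chirp-echo phenomenology: ``phi0`` is the
offset-independent echo phase (read at the spin closest to Omega = 0),
``delta_phi(Omega)`` the residual offset-dependent phase after subtracting
phi0, ``phi_p`` the fitted parabolic phase-roll coefficient, and the
fidelity is the weight-normalized magnitude of the summed transverse
magnetization (1 when every spin is aligned in phase at the echo time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pulse_shapes import (
    ChirpPulse,
    Waveform,
    amplitude_for_qcrit,
    sample_waveform,
)
from .sequences import Sequence, make_variant, refocused_train

__all__ = [
    "SpinEnsemble",
    "B1Distribution",
    "EchoRecord",
    "propagate_pulse",
    "propagate_delay",
    "run_sequence",
    "phi0_vs_qcrit",
    "echo_vs_qcrit",
    "sifter_amplitude_sweep",
]

_TWO_PI_MHZ = 2.0 * np.pi * 1e6  # MHz -> rad/s


@dataclass
class SpinEnsemble:
    """Offsets (rad/s) and unit magnetization vectors, initialized at +z."""

    offsets: np.ndarray
    M: np.ndarray = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.M is None:
            self.M = np.zeros((self.offsets.size, 3))
            self.M[:, 2] = 1.0
        else:
            self.M = np.asarray(self.M, dtype=float)
            if self.M.shape != (self.offsets.size, 3):
                raise ValueError("M must have shape (n_offsets, 3)")

    @classmethod
    def uniform(cls, n: int = 1000, span: tuple[float, float] = (-100.0, 100.0)):
        """``n`` spins with offsets uniformly spaced over ``span`` (MHz)."""
        nu = np.linspace(span[0], span[1], n)
        return cls(offsets=nu * _TWO_PI_MHZ)

    @property
    def mxy(self) -> np.ndarray:
        return self.M[:, 0] + 1j * self.M[:, 1]

    def copy(self) -> "SpinEnsemble":
        return SpinEnsemble(offsets=self.offsets.copy(), M=self.M.copy())


@dataclass(frozen=True)
class B1Distribution:
    """Half-Gaussian distribution of relative B1 amplitudes.

    Most of the sample sits at the full field (scale 1); the resonator edges
    see less.  Scales live on ``[1 - trunc*sigma, 1]`` with weights
    proportional to ``exp(-(1 - scale)^2 / (2 sigma^2))``, normalized to sum
    to one.  ``sigma = 0`` degenerates to the single full-amplitude scale.
    """

    sigma: float
    scales: np.ndarray = field(default=None)
    weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.scales is None:
            if self.sigma == 0:
                object.__setattr__(self, "scales", np.array([1.0]))
                object.__setattr__(self, "weights", np.array([1.0]))
            else:
                s = np.linspace(max(1.0 - 4.0 * self.sigma, 1e-6), 1.0, 21)
                w = np.exp(-((1.0 - s) ** 2) / (2.0 * self.sigma**2))
                object.__setattr__(self, "scales", s)
                object.__setattr__(self, "weights", w / w.sum())


@dataclass
class EchoRecord:
    """Detected complex transient and the echo observables."""

    times: np.ndarray            # ns after the last pulse center
    transient: np.ndarray        # weight-normalized sum of M_xy
    echo_time: float             # ns, |transient| maximum (parabolic refine)
    phi0: float                  # rad, phase of the Omega ~ 0 spin at echo
    offsets: np.ndarray          # rad/s
    delta_phi: np.ndarray        # rad, unwrapped per-offset phase - phi0
    phi_p: float                 # rad/(rad/s)^2, fitted parabolic roll
    fidelity: float              # |sum w M_xy| / sum w at the echo time
    amplitudes: np.ndarray       # per-offset |M_xy| at the echo time

    def band_fidelity(self, frac: float = 0.6) -> float:
        """Fidelity restricted to the central ``frac`` of the offset range."""
        lo, hi = np.quantile(self.offsets, [(1 - frac) / 2, (1 + frac) / 2])
        sel = (self.offsets >= lo) & (self.offsets <= hi)
        phases = np.exp(1j * (self.delta_phi + self.phi0))
        return float(np.abs((self.amplitudes[sel] * phases[sel]).mean()))

    def export(self, path) -> None:
        """Write (time ns, real, imag) columns plus a JSON sidecar with the
        scalar echo metrics."""
        np.savetxt(
            path,
            np.column_stack(
                [self.times, self.transient.real, self.transient.imag]
            ),
            header="time_ns real imag",
        )
        meta = dict(
            echo_time_ns=self.echo_time, phi0_rad=self.phi0,
            fidelity=self.fidelity, phi_p=self.phi_p,
        )
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _rotate_step(M, wx, wy, wz, dt):
    """Right-handed axis-angle rotation of every row of ``M`` about the
    per-spin field (wx, wy, wz) [rad/s] for ``dt`` seconds."""
    norm = np.sqrt(wx * wx + wy * wy + wz * wz)
    theta = norm * dt
    c = np.cos(theta)
    s = np.sin(theta)
    inv = np.where(norm > 0.0, 1.0 / np.where(norm > 0.0, norm, 1.0), 0.0)
    kx, ky, kz = wx * inv, wy * inv, wz * inv
    mx, my, mz = M[:, 0], M[:, 1], M[:, 2]
    dot = kx * mx + ky * my + kz * mz
    cx = ky * mz - kz * my
    cy = kz * mx - kx * mz
    cz = kx * my - ky * mx
    omc = (1.0 - c) * dot
    M[:, 0] = c * mx + s * cx + omc * kx
    M[:, 1] = c * my + s * cy + omc * ky
    M[:, 2] = c * mz + s * cz + omc * kz


def propagate_pulse(
    ens: SpinEnsemble,
    wf: Waveform,
    scale: float | np.ndarray = 1.0,
    phase: float = 0.0,
) -> SpinEnsemble:
    """Propagate the ensemble through a sampled pulse (in place).

    ``scale`` multiplies the pulse amplitude (scalar, or one factor per
    spin, for B1-inhomogeneity averaging); ``phase`` is the pulse phase tag
    (0 for x, pi/2 for y).  Each waveform interval is treated as a constant
    field and applied as an exact rotation; a per-step rotation angle above
    pi/4 raises an under-sampling error.
    """
    dt = wf.dt * 1e-9
    samples = 0.5 * (wf.samples[:-1] + wf.samples[1:]) * np.exp(1j * phase)
    w1_max = np.abs(samples).max(initial=0.0) * np.max(scale)
    wz_max = np.abs(ens.offsets).max(initial=0.0)
    if np.hypot(w1_max, wz_max) * dt > np.pi / 4.0:
        raise ValueError(
            "per-step rotation exceeds pi/4; decrease the waveform dt"
        )
    M = ens.M
    wz = ens.offsets
    for sample in samples:
        _rotate_step(M, scale * sample.real, scale * sample.imag, wz, dt)
    return ens


def propagate_delay(ens: SpinEnsemble, tau: float) -> SpinEnsemble:
    """Free evolution for ``tau`` ns: analytic z-rotation by Omega*tau."""
    if tau < 0:
        raise ValueError("delay must be non-negative")
    if tau == 0:
        return ens
    rot = np.exp(1j * ens.offsets * tau * 1e-9)
    mxy = (ens.M[:, 0] + 1j * ens.M[:, 1]) * rot
    ens.M[:, 0] = mxy.real
    ens.M[:, 1] = mxy.imag
    return ens


def _propagate_elements(seq: Sequence, offsets, scale, dt_pulse):
    """Run the sequence for one B1 scale (scalar or per-spin array).

    Returns per-offset complex M_xy referenced to the *end edge* of the last
    pulse, plus the half-length of the last pulse (ns).
    """
    ens = SpinEnsemble(offsets=offsets)
    n = len(seq.pulses)
    for i, (pulse, phase) in enumerate(zip(seq.pulses, seq.phases)):
        wf = sample_waveform(pulse, dt_pulse)
        propagate_pulse(ens, wf, scale=scale, phase=phase)
        if i < n - 1:
            gap = seq.gaps[i]
            propagate_delay(ens, gap)
    return ens.mxy, seq.pulses[-1].tp / 2.0


def run_sequence(
    seq: Sequence,
    *,
    offsets: np.ndarray | None = None,
    n_spins: int = 1000,
    offset_span: tuple[float, float] = (-100.0, 100.0),
    b1: B1Distribution | None = None,
    detection_window: tuple[float, float] | None = None,
    n_detect: int = 257,
    dt_pulse: float | None = None,
) -> EchoRecord:
    """Simulate the sequence and detect the echo transient.

    ``offsets`` (rad/s) overrides the default uniform ensemble of
    ``n_spins`` spins over ``offset_span`` (MHz).  ``detection_window`` is
    (start, stop) in ns after the last pulse center and must start after the
    last pulse has ended; it defaults to a window centered on the nominal
    echo time.  With a :class:`B1Distribution`, the simulation is repeated
    per amplitude scale and the transients added with the distribution
    weights (the transient is exactly the weighted sum of the per-scale
    transients).
    """
    if offsets is None:
        offsets = SpinEnsemble.uniform(n_spins, offset_span).offsets
    offsets = np.asarray(offsets, dtype=float)
    dist = b1 if b1 is not None else B1Distribution(0.0)

    half_last = seq.pulses[-1].tp / 2.0
    if detection_window is None:
        span = max(0.6 * seq.echo_delay, 4.0 * seq.pulses[-1].tp)
        # a uniform offset grid makes the discrete transient periodic with
        # period 1/(grid spacing); keep the default window below that so the
        # echo cannot alias to a spurious earlier time
        d_off = np.diff(np.sort(offsets))
        if d_off.size and np.allclose(d_off, d_off[0], rtol=1e-6):
            t_alias = 1e9 * 2.0 * np.pi / d_off[0]
            span = min(span, 0.8 * t_alias)
        lo = max(seq.echo_delay - span / 2.0, half_last)
        detection_window = (lo, seq.echo_delay + span / 2.0)
    t0, t1 = detection_window
    if t0 < half_last - 1e-9:
        raise ValueError(
            f"detection window starts at {t0} ns but the last pulse ends "
            f"{half_last} ns after its center"
        )

    # joint propagation over (scale x offset); aggregate per offset
    n_off = offsets.size
    big_off = np.tile(offsets, dist.scales.size)
    big_scale = np.repeat(dist.scales, n_off)
    mxy, _ = _propagate_elements(seq, big_off, big_scale, dt_pulse)
    w = np.repeat(dist.weights, n_off)
    agg = (mxy * w).reshape(dist.scales.size, n_off).sum(axis=0)
    # agg: b1-weighted M_xy per offset at the last pulse's end edge

    times = np.linspace(t0, t1, n_detect)
    phase = np.exp(1j * np.outer(offsets, (times - half_last) * 1e-9))
    transient = (agg @ phase) / n_off

    mag = np.abs(transient)
    k = int(np.argmax(mag))
    if k == 0 or k == mag.size - 1:
        raise ValueError(
            "no echo maximum inside the detection window; widen the window"
        )
    # 3-point parabolic refinement of the echo time and amplitude
    y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    echo_time = float(times[k] + shift * (times[1] - times[0]))
    fid = float(y1 - (y2 - y0) ** 2 / (8.0 * denom)) if denom != 0 else float(y1)

    order = np.argsort(offsets)
    lo_q, hi_q = np.quantile(offsets, [0.2, 0.8])
    c_sel = (offsets[order] >= lo_q) & (offsets[order] <= hi_q)
    # the per-offset phases are referenced to the phase-stationary point,
    # which can sit a fraction of a detection sample off the |transient|
    # maximum; polish it so delta_phi carries no artificial linear ramp
    t_phase = echo_time
    for _ in range(2):
        at = agg * np.exp(1j * offsets * (t_phase - half_last) * 1e-9)
        ph = np.unwrap(np.angle(at[order]))
        sl = np.polyfit(offsets[order][c_sel], ph[c_sel], 1)[0]  # rad/(rad/s)
        t_phase -= sl * 1e9
    if not times[0] <= t_phase <= times[-1]:
        # near-null echoes have no well-defined stationary point; reference
        # the phases at the amplitude maximum instead
        t_phase = echo_time

    at_echo = agg * np.exp(1j * offsets * (t_phase - half_last) * 1e-9)
    phases = np.unwrap(np.angle(at_echo[order]))
    i0 = int(np.argmin(np.abs(offsets[order])))
    phi0 = float(np.angle(at_echo[order][i0]))
    delta = phases - phases[i0] + 0.0
    # parabolic roll over the central 60 % of the band
    coeff = np.polyfit(offsets[order][c_sel], delta[c_sel], 2)

    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return EchoRecord(
        times=times,
        transient=transient,
        echo_time=echo_time,
        phi0=phi0,
        offsets=offsets,
        delta_phi=delta[inv],
        phi_p=float(coeff[0]),
        fidelity=fid,
        amplitudes=np.abs(at_echo),
    )


@dataclass
class QcritCurve:
    """phi0 or echo amplitude sampled over a Q grid."""

    q: np.ndarray
    values: np.ndarray
    slope: float | None = None   # rad per unit Q over the linear window
    fit_window: tuple[float, float] = (4.0, 10.0)


def _default_phi0_offsets(sw: float, n: int = 41) -> np.ndarray:
    span = 0.25 * sw
    return np.linspace(-span, span, n) * _TWO_PI_MHZ


def phi0_vs_qcrit(
    template: str,
    q_grid: np.ndarray,
    *,
    tp_unit: float = 100.0,
    sw: float = 500.0,
    taus=None,
    n_spins: int = 41,
    fit_window: tuple[float, float] = (4.0, 10.0),
    dt_pulse: float | None = None,
) -> QcritCurve:
    """Echo phase at the sweep center as a function of the pi-pulse Q.

    phi0 grows near-linearly with Q (Bloch-Siegert-type dynamic phase); the
    returned slope is a linear fit over ``fit_window``, chosen above the
    low-Q region where coherence inversion is still incomplete.  A phase
    step above pi between adjacent grid points raises, since the unwrapping
    would be ambiguous — refine the grid.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    taus = taus if taus is not None else _default_taus(template, tp_unit)
    offs = _default_phi0_offsets(sw, n_spins)
    raw = []
    for q in q_grid:
        seq = _build(template, tp_unit, sw, q, taus)
        rec = run_sequence(seq, offsets=offs, dt_pulse=dt_pulse)
        raw.append(rec.phi0)
    phi = np.unwrap(np.asarray(raw))
    if np.any(np.abs(np.diff(phi)) > np.pi):
        raise ValueError(
            "phi0 jumps by more than pi between Q grid points; refine the grid"
        )
    lo, hi = fit_window
    sel = (q_grid >= lo) & (q_grid <= hi)
    slope = float(np.polyfit(q_grid[sel], phi[sel], 1)[0]) if sel.sum() >= 2 else None
    return QcritCurve(q=q_grid, values=phi, slope=slope, fit_window=fit_window)


def echo_vs_qcrit(
    template: str,
    q_grid: np.ndarray,
    b1: B1Distribution | None = None,
    *,
    tp_unit: float = 100.0,
    sw: float = 500.0,
    taus=None,
    n_spins: int = 201,
    offset_span: tuple[float, float] = (-100.0, 100.0),
    dt_pulse: float | None = None,
) -> QcritCurve:
    """Absolute echo intensity versus the shared Q of the pi pulses.

    The pi/2 amplitude stays pinned to an exact pi/2 flip.  Under B1
    inhomogeneity the curve shows an interior maximum followed by a decline
    caused by the spread of the dynamic phase shifts.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    taus = taus if taus is not None else _default_taus(template, tp_unit)
    vals = []
    for q in q_grid:
        seq = _build(template, tp_unit, sw, q, taus)
        rec = run_sequence(
            seq, n_spins=n_spins, offset_span=offset_span, b1=b1,
            dt_pulse=dt_pulse,
        )
        vals.append(rec.fidelity)
    return QcritCurve(q=q_grid, values=np.asarray(vals))


@dataclass
class AmplitudeSweep:
    """SIFTER echo amplitude and the two-pulse echo phase at the third pulse."""

    q: np.ndarray
    echo: np.ndarray
    phi0_third: np.ndarray
    maxima: np.ndarray   # indices into q
    minima: np.ndarray


def sifter_amplitude_sweep(
    q_grid: np.ndarray,
    *,
    template: str = "sifter_2221",
    tp_unit: float = 100.0,
    sw: float = 500.0,
    tau1: float | None = None,
    tau2: float | None = None,
    n_spins: int = 201,
    offset_span: tuple[float, float] = (-100.0, 100.0),
    dt_pulse: float | None = None,
) -> AmplitudeSweep:
    """Sweep the joint pi-pulse amplitude of a SIFTER sequence.

    Both pi pulses keep the same Q (for 2:1 lengths, a 1:sqrt(2) amplitude
    relation), so the sweep is parametrized by Q.  The echo amplitude
    oscillates because the first-echo phase phi0 at the (pi/2)y pulse must
    be an odd multiple of pi/2 for full dipolar refocusing: maxima occur at
    half-integer multiples of pi, minima at integer multiples.  The
    companion curve is phi0 of the two-pulse echo evaluated exactly at the
    third pulse's center.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if tau1 is None:
        tau1 = 4.0 * tp_unit
    if tau2 is None:
        tau2 = tau1
    offs = np.linspace(offset_span[0], offset_span[1], n_spins) * _TWO_PI_MHZ
    echo, phi3_raw = [], []
    for q in q_grid:
        seq = make_variant(template, tp_unit, sw, q_pi=q, taus=(tau1, tau2))
        rec = run_sequence(seq, offsets=offs, dt_pulse=dt_pulse)
        echo.append(rec.fidelity)
        # first two pulses only, phase read at the third pulse's center time
        sub = Sequence(
            name="sifter_first_echo",
            pulses=seq.pulses[:2], phases=seq.phases[:2],
            delays=seq.delays[:1], echo_delay=seq.delays[1],
            pathways=seq.pathways[:0], taus=seq.taus, params={},
        )
        mxy, half = _propagate_elements(sub, offs, 1.0, dt_pulse)
        at_third = mxy * np.exp(1j * offs * (seq.delays[1] - half) * 1e-9)
        i0 = int(np.argmin(np.abs(offs)))
        phi3_raw.append(float(np.angle(at_third[i0])))
    echo = np.asarray(echo)
    phi3 = np.unwrap(np.asarray(phi3_raw))
    interior = np.arange(1, q_grid.size - 1)
    maxima = interior[
        (echo[interior] > echo[interior - 1]) & (echo[interior] > echo[interior + 1])
    ]
    minima = interior[
        (echo[interior] < echo[interior - 1]) & (echo[interior] < echo[interior + 1])
    ]
    return AmplitudeSweep(
        q=q_grid, echo=echo, phi0_third=phi3, maxima=maxima, minima=minima
    )


def _default_taus(template: str, tp_unit: float):
    from .sequences import TEMPLATES

    tpl = TEMPLATES.get(template)
    base = 4.0 * tp_unit
    if tpl is None:
        return (base,)
    return (base,) * tpl.n_taus


def _build(template: str, tp_unit: float, sw: float, q: float, taus) -> Sequence:
    if template.startswith("refocused_train_"):
        n_pi = int(template.removeprefix("refocused_train_").removesuffix("pi"))
        return refocused_train(n_pi, tp_unit, sw, q_pi=q, tau=np.atleast_1d(taus)[0])
    return make_variant(template, tp_unit, sw, q_pi=q, taus=taus)
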