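"""WURST chirp pulses: envelopes, phase functions, adiabaticity and flip angles.

A linear-frequency chirp with a WURST (wideband, uniform rate, smooth
truncation) amplitude profile is the workhorse pulse for broadband excitation
in pulsed EPR.  The complex pulse is ``S(t) = omega1(t) * exp(i*phi(t))`` on
the symmetric time coordinate ``t in [-tp/2, +tp/2]``, with

* amplitude   ``omega1(t) = omega1_max * (1 - |sin(pi t / tp)|**n)``,
* frequency   ``d(phi)/dt = s * 2*pi*(SW/tp) * t + 2*pi*carrier_offset``,
* phase       the integral of the instantaneous frequency, zero at ``t = 0``.

Two dimensionless numbers control the spin response: the critical
adiabaticity ``Q = omega1_max**2 * tp / (2*pi*SW)`` which sets the effective
flip angle ``beta = arccos(2*exp(-pi*Q/2) - 1)``, and the time-bandwidth
product ``TBP = tp*SW`` which controls the smoothness of the excitation
profile (values below ~30 are best avoided).

Unit conventions
----------------
Public interfaces use bench units: nanoseconds for times, megahertz for
frequencies and nutation amplitudes, radians for phases and flip angles.
``Waveform.samples`` carries the complex amplitude in rad/s because that is
what enters the Bloch equations directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ChirpPulse",
    "Waveform",
    "ResonatorProfile",
    "wurst_envelope",
    "instantaneous_frequency",
    "phase_function",
    "qcrit",
    "amplitude_for_qcrit",
    "time_bandwidth_product",
    "flip_angle",
    "qcrit_for_flip",
    "sample_waveform",
    "apply_transfer_correction",
    "export_waveform",
]

#: MHz**2 * ns / MHz -> dimensionless prefactor for Q = 2*pi*nu1**2*tp/SW (SI)
_Q_UNIT = 2.0e-3 * np.pi

PI_HALF_QCRIT = 2.0 * np.log(2.0) / np.pi  # Q for an exact pi/2 flip


@dataclass(frozen=True)
class ChirpPulse:
    """Parametric WURST chirp pulse.

    Parameters
    ----------
    tp : float
        Pulse duration (ns).
    sweep : float
        Sweep width SW of the linear frequency chirp (MHz).
    nu1 : float
        Peak nutation amplitude ``omega1_max / 2 pi`` (MHz).
    n : float
        WURST steepness index (>= 1); larger values give a flatter top.
    sign : int
        Sweep direction: +1 sweeps low-to-high frequency, -1 the reverse.
    carrier_offset : float
        Center of the sweep relative to the carrier frequency (MHz).
    phi_start : float
        Constant phase offset added to the chirp phase (rad).
    role : str or None
        Nominal flip-angle tag, ``"pi/2"`` or ``"pi"``; bookkeeping only.
    """

    tp: float
    sweep: float
    nu1: float
    n: float = 16.0
    sign: int = 1
    carrier_offset: float = 0.0
    phi_start: float = 0.0
    role: str | None = None

    def __post_init__(self) -> None:
        if self.tp <= 0:
            raise ValueError(f"pulse duration must be positive, got tp={self.tp}")
        if self.sweep <= 0:
            raise ValueError(f"sweep width must be positive, got sweep={self.sweep}")
        if self.n < 1:
            raise ValueError(f"WURST index must be >= 1, got n={self.n}")
        if self.nu1 < 0:
            raise ValueError(f"nutation amplitude must be >= 0, got nu1={self.nu1}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sweep sign must be +1 or -1, got {self.sign}")
        if self.role not in (None, "pi/2", "pi"):
            raise ValueError(f"role must be 'pi/2', 'pi' or None, got {self.role!r}")

    @property
    def omega1_max(self) -> float:
        """Peak nutation amplitude in rad/s."""
        return 2.0 * np.pi * self.nu1 * 1e6

    @property
    def qcrit(self) -> float:
        """Critical adiabaticity of this pulse."""
        return qcrit(self.nu1, self.tp, self.sweep)

    @property
    def tbp(self) -> float:
        """Time-bandwidth product tp*SW."""
        return time_bandwidth_product(self.tp, self.sweep)

    def conjugate(self) -> "ChirpPulse":
        """The same pulse with the sweep direction reversed."""
        return replace(self, sign=-self.sign)


@dataclass(frozen=True)
class Waveform:
    """Sampled complex pulse envelope.

    ``times`` (ns) is a uniform grid spanning exactly ``[-tp/2, +tp/2]``;
    ``samples`` is ``omega1(t)*exp(i*phi(t))`` in rad/s; ``dt`` is the sample
    spacing in ns.
    """

    times: np.ndarray
    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if self.times.shape != self.samples.shape:
            raise ValueError("times and samples must have matching shapes")

    @property
    def amplitude(self) -> np.ndarray:
        """|samples| in rad/s."""
        return np.abs(self.samples)

    @property
    def phase(self) -> np.ndarray:
        """Unwrapped argument of the samples (rad)."""
        return np.unwrap(np.angle(self.samples))

    @property
    def duration(self) -> float:
        """Total span of the time grid (ns)."""
        return float(self.times[-1] - self.times[0])


class ResonatorProfile:
    """Normalized nutation response of the resonator versus frequency.

    Obtained experimentally from Rabi nutation experiments at stepped
    frequencies; here it is just a strictly increasing frequency grid (MHz,
    relative to the carrier) with the nutation amplitude per frequency
    normalized so that the maximum equals one.
    """

    def __init__(self, freqs: np.ndarray, response: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        response = np.asarray(response, dtype=float)
        if freqs.ndim != 1 or freqs.shape != response.shape:
            raise ValueError("freqs and response must be 1-D arrays of equal length")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(response <= 0):
            raise ValueError("resonator response must be positive everywhere")
        self.freqs = freqs
        self.response = response / response.max()

    def __call__(self, freq) -> np.ndarray:
        """Interpolated response at ``freq`` (MHz)."""
        return np.interp(freq, self.freqs, self.response)

    @classmethod
    def from_file(cls, path) -> "ResonatorProfile":
        """Read a two-column (frequency MHz, response) text table.

        Comment lines start with ``#``; any whitespace or comma delimiter.
        """
        data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
        if data.shape[1] < 2:
            data = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
        return cls(data[:, 0], data[:, 1])

    def to_file(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.freqs, self.response]),
            header="frequency_MHz normalized_response",
        )


def wurst_envelope(pulse: ChirpPulse, t) -> np.ndarray:
    """WURST amplitude fraction ``1 - |sin(pi t / tp)|**n`` at time ``t`` (ns).

    Returns the dimensionless envelope in [0, 1]; multiply by
    ``pulse.omega1_max`` for the physical amplitude.  ``t`` outside
    ``[-tp/2, +tp/2]`` raises ``ValueError``.
    """
    t = np.asarray(t, dtype=float)
    half = pulse.tp / 2.0
    if np.any(t < -half - 1e-12) or np.any(t > half + 1e-12):
        raise ValueError(
            f"sample time outside pulse support [-{half} ns, +{half} ns]"
        )
    return 1.0 - np.abs(np.sin(np.pi * t / pulse.tp)) ** pulse.n


def instantaneous_frequency(pulse: ChirpPulse, t) -> np.ndarray:
    """Instantaneous frequency offset from the carrier at ``t`` (ns), in MHz.

    Linear in time: ``s * (SW/tp) * t + carrier_offset``.
    """
    t = np.asarray(t, dtype=float)
    half = pulse.tp / 2.0
    if np.any(t < -half - 1e-12) or np.any(t > half + 1e-12):
        raise ValueError(
            f"sample time outside pulse support [-{half} ns, +{half} ns]"
        )
    return pulse.sign * (pulse.sweep / pulse.tp) * t + pulse.carrier_offset


def phase_function(pulse: ChirpPulse, t) -> np.ndarray:
    """Chirp phase (rad) at time ``t`` (ns), zero at the pulse center.

    Closed form of the integral of the instantaneous angular frequency:
    ``phi(t) = s*pi*(SW/tp)*t**2 + 2*pi*carrier_offset*t + phi_start``
    (with the MHz*ns -> rad factor of 1e-3 applied internally).
    """
    t = np.asarray(t, dtype=float)
    quad = pulse.sign * np.pi * (pulse.sweep / pulse.tp) * t**2 * 1e-3
    lin = 2.0 * np.pi * pulse.carrier_offset * t * 1e-3
    return quad + lin + pulse.phi_start


def qcrit(nu1: float, tp: float, sweep: float) -> float:
    """Critical adiabaticity ``omega1**2 * tp / (2*pi*SW)``.

    Parameters are the peak nutation amplitude ``nu1`` (MHz), pulse length
    ``tp`` (ns) and sweep width ``sweep`` (MHz).  The conversion to angular
    frequency for omega1 (and not for SW) is applied internally — this is
    the classic 2*pi pitfall of the formula.
    """
    if nu1 <= 0 or tp <= 0 or sweep <= 0:
        raise ValueError("qcrit requires positive nu1, tp and sweep")
    return _Q_UNIT * nu1**2 * tp / sweep


def amplitude_for_qcrit(q: float, tp: float, sweep: float) -> float:
    """Nutation amplitude nu1 (MHz) giving adiabaticity ``q`` at (tp ns, SW MHz)."""
    if q <= 0 or tp <= 0 or sweep <= 0:
        raise ValueError("amplitude_for_qcrit requires positive arguments")
    return float(np.sqrt(q * sweep / (_Q_UNIT * tp)))


def time_bandwidth_product(tp: float, sweep: float) -> float:
    """Time-bandwidth product ``tp * SW`` (dimensionless; tp ns, SW MHz)."""
    if tp <= 0 or sweep <= 0:
        raise ValueError("time_bandwidth_product requires positive arguments")
    return tp * sweep * 1e-3


def flip_angle(q) -> np.ndarray:
    """Effective flip angle ``beta = arccos(2*exp(-pi*Q/2) - 1)`` (rad).

    Monotone in Q: zero at Q = 0, asymptotically approaching pi — a chirp
    pulse cannot flip polarization or coherence by more than pi.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("critical adiabaticity must be non-negative")
    return np.arccos(2.0 * np.exp(-np.pi * q / 2.0) - 1.0)


def qcrit_for_flip(beta: float) -> float:
    """Invert the flip-angle formula: Q = -(2/pi)*ln((cos(beta) + 1)/2).

    ``beta = pi`` is unreachable with a finite amplitude and raises.
    For ``beta = pi/2`` this evaluates to ``2*ln(2)/pi ~= 0.44``.
    """
    if beta < 0 or beta >= np.pi:
        raise ValueError(
            "flip angle must lie in [0, pi); beta = pi is reached only "
            "asymptotically by a chirp pulse"
        )
    return -(2.0 / np.pi) * np.log((np.cos(beta) + 1.0) / 2.0)


def _default_dt(pulse: ChirpPulse) -> float:
    """Default sample spacing (ns): >= 1000 samples per pulse and >= 16
    samples per period of the fastest oscillation in the envelope."""
    f_max = pulse.sweep + pulse.nu1 / 2.0 + abs(pulse.carrier_offset)
    return min(pulse.tp / 1000.0, 1e3 / (16.0 * f_max))


def _max_dt(pulse: ChirpPulse) -> float:
    """Largest spacing keeping the per-step phase advance below pi/8 at the
    band edge."""
    f_edge = pulse.sweep / 2.0 + abs(pulse.carrier_offset) + pulse.nu1
    return 1e3 / (16.0 * f_edge)


def sample_waveform(pulse: ChirpPulse, dt: float | None = None) -> Waveform:
    """Sample the complex envelope ``omega1(t)*exp(i*phi(t))`` on a uniform grid.

    The grid spans exactly ``[-tp/2, +tp/2]``.  ``dt`` (ns) defaults to a
    spacing giving at least 1000 samples per pulse and 16 samples per fastest
    oscillation; an explicit ``dt`` that would let the per-step phase advance
    exceed pi/8 at the band edge is rejected.
    """
    if dt is None:
        dt = _default_dt(pulse)
    allowed = _max_dt(pulse)
    if dt > allowed * (1 + 1e-9):
        raise ValueError(
            f"dt={dt:.4g} ns undersamples the chirp; use dt <= {allowed:.4g} ns"
        )
    nseg = max(int(np.ceil(pulse.tp / dt)), 2)
    times = np.linspace(-pulse.tp / 2.0, pulse.tp / 2.0, nseg + 1)
    env = wurst_envelope(pulse, times) * pulse.omega1_max
    phi = phase_function(pulse, times)
    return Waveform(times=times, samples=env * np.exp(1j * phi), dt=pulse.tp / nseg)


def apply_transfer_correction(
    wf: Waveform,
    pulse: ChirpPulse,
    profile: ResonatorProfile,
    floor: float = 0.05,
) -> Waveform:
    """Pre-compensate the resonator transfer function (amplitude only).

    Each sample's amplitude is divided by the normalized resonator response
    at that sample's instantaneous frequency and the result rescaled so the
    peak amplitude again equals ``omega1_max``; the phase is untouched.  A
    response below ``floor`` inside the swept band raises, preventing an
    unbounded amplitude boost.  Frequency-sweep warping is deliberately not
    applied.
    """
    lo = pulse.carrier_offset - pulse.sweep / 2.0
    hi = pulse.carrier_offset + pulse.sweep / 2.0
    if profile.freqs[0] > lo + 1e-9 or profile.freqs[-1] < hi - 1e-9:
        raise ValueError(
            f"resonator profile covers [{profile.freqs[0]}, {profile.freqs[-1]}] MHz "
            f"but the pulse sweeps [{lo}, {hi}] MHz"
        )
    freqs = instantaneous_frequency(pulse, wf.times)
    resp = profile(freqs)
    if np.any(resp < floor):
        raise ValueError(
            f"resonator response drops below the boost floor ({floor}) inside "
            "the swept band; correction would require an unbounded amplitude"
        )
    corrected = wf.samples / resp
    peak = np.abs(corrected).max()
    if peak > 0:
        corrected *= pulse.omega1_max / peak
    return Waveform(times=wf.times, samples=corrected, dt=wf.dt)


def export_waveform(wf: Waveform, path) -> None:
    """Write (time ns, real MHz, imag MHz) columns for AWG-style consumption."""
    nu = wf.samples / (2.0 * np.pi * 1e6)
    np.savetxt(
        path,
        np.column_stack([wf.times, nu.real, nu.imag]),
        header="time_ns real_MHz imag_MHz",
    )
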