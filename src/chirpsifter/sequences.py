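"""Named chirp-pulse sequence templates and 2D timing schedules.

Templates cover the standard broadband-EPR building blocks: the 2:1 chirp
Hahn echo (Boehlen-Bodenhausen scheme), the 2:2:1 refocused echo (ABSTRUSE),
the diagnostic 2:2:2 refocused echo, the four-pulse SIFTER family
(2:2:2:1 standard, 2:2:6:3 dual-echo, 2:3:1:4 dispersion-free solid echo),
the Carr-Purcell-style asymmetric six-pulse SIFTER (2:2:2:2:3:2), and the
SIDRE background references obtained by omitting the (pi/2)y pulse.

Timing convention: all delays are measured between pulse *centers*.  For
linear chirps this makes the refocusing-condition arithmetic exact (a spin
at the sweep center is acted on exactly at the pulse center).  Note that
edge-to-edge delays are the more common bench convention; convert before
comparing with spectrometer settings.

Pulse amplitudes are set from the critical adiabaticity: pi/2-role pulses
get Q = 2*ln(2)/pi exactly, pi-role pulses share a single configurable Q so
their dynamic phase shifts compensate (for lengths 2:1 this yields the
1:sqrt(2) amplitude relation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pulse_shapes import (
    ChirpPulse,
    PI_HALF_QCRIT,
    amplitude_for_qcrit,
)
from .ratio_solver import CoherencePathway

__all__ = [
    "Sequence",
    "SifterSchedule",
    "TEMPLATES",
    "make_variant",
    "make_sifter_2221",
    "refocused_train",
    "schedule_2d",
]

X = 0.0
Y = np.pi / 2.0


@dataclass(frozen=True)
class _Template:
    ratios: tuple[int, ...]
    roles: tuple[str, ...]
    phases: tuple[float, ...]
    signs: tuple[int, ...]
    # delay layout as coefficient rows over (tau1..tau4): center-to-center
    # delay j = sum_k coeff[j][k] * tau_k ; echo similarly
    delay_coeffs: tuple[tuple[int, ...], ...]
    echo_coeffs: tuple[int, ...]
    pathways: tuple[CoherencePathway, ...]
    n_taus: int = 2
    sweep_signs_assumed: bool = False


def _p(orders):
    return CoherencePathway.from_orders(orders)


_SIFTER_MAIN = _p([0, 1, -1, -1, 1])
_SIFTER_INVERTED = _p([0, 1, -1, 1, -1])

TEMPLATES: dict[str, _Template] = {
    "hahn_21": _Template(
        ratios=(2, 1), roles=("pi/2", "pi"), phases=(X, X), signs=(1, 1),
        delay_coeffs=((1, 0),), echo_coeffs=(1, 0),
        pathways=(_p([0, 1, -1]),), n_taus=1,
    ),
    "abstruse_221": _Template(
        ratios=(2, 2, 1), roles=("pi/2", "pi", "pi"), phases=(X, X, X),
        signs=(1, 1, 1),
        delay_coeffs=((1, 0), (1, 1)), echo_coeffs=(0, 1),
        pathways=(_p([0, 1, -1, 1]),),
    ),
    # 2:2:2 does not refocus the parabolic phase roll; it is the diagnostic
    # sequence whose two equal-TBP pi pulses cancel their Q-dependent phase.
    "refocused_222": _Template(
        ratios=(2, 2, 2), roles=("pi/2", "pi", "pi"), phases=(X, X, X),
        signs=(1, 1, 1),
        delay_coeffs=((1, 0), (1, 1)), echo_coeffs=(0, 1),
        pathways=(),
    ),
    "sifter_2221": _Template(
        ratios=(2, 2, 2, 1), roles=("pi/2", "pi", "pi/2", "pi"),
        phases=(X, X, Y, X), signs=(1, 1, 1, 1),
        delay_coeffs=((1, 0), (1, 0), (0, 1)), echo_coeffs=(0, 1),
        pathways=(_SIFTER_MAIN,), sweep_signs_assumed=True,
    ),
    "sifter_2263": _Template(
        ratios=(2, 2, 6, 3), roles=("pi/2", "pi", "pi/2", "pi"),
        phases=(X, X, Y, X), signs=(1, -1, -1, -1),
        delay_coeffs=((1, 0), (1, 0), (0, 1)), echo_coeffs=(0, 1),
        pathways=(_SIFTER_MAIN, _SIFTER_INVERTED),
    ),
    "sifter_2314": _Template(
        ratios=(2, 3, 1, 4), roles=("pi/2", "pi", "pi/2", "pi"),
        phases=(X, X, Y, X), signs=(1, -1, 1, -1),
        delay_coeffs=((1, 0), (1, 0), (0, 1)), echo_coeffs=(0, 1),
        pathways=(_SIFTER_MAIN,),
    ),
    "sixpulse_222232": _Template(
        ratios=(2, 2, 2, 2, 3, 2),
        roles=("pi/2", "pi", "pi/2", "pi", "pi", "pi"),
        phases=(X, X, Y, X, X, X), signs=(1, 1, 1, 1, 1, 1),
        delay_coeffs=((1, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0),
                      (0, 1, 1, 0), (0, 0, 1, 1)),
        echo_coeffs=(0, 0, 0, 1),
        pathways=(_p([0, 1, -1, -1, 1, -1, 1]),),
        n_taus=4, sweep_signs_assumed=True,
    ),
    "sidre_3p": _Template(
        ratios=(2, 2, 1), roles=("pi/2", "pi", "pi"), phases=(X, X, X),
        signs=(1, 1, 1),
        delay_coeffs=((1, 0), (1, 1)), echo_coeffs=(0, 1),
        pathways=(_p([0, 1, -1, 1]),),
    ),
    "sidre_5p": _Template(
        ratios=(2, 2, 2, 3, 2),
        roles=("pi/2", "pi", "pi", "pi", "pi"), phases=(X, X, X, X, X),
        signs=(1, 1, 1, 1, 1),
        delay_coeffs=((1, 0, 0, 0), (1, 1, 0, 0), (0, 1, 1, 0),
                      (0, 0, 1, 1)),
        echo_coeffs=(0, 0, 0, 1),
        pathways=(_p([0, 1, -1, 1, -1, 1]),),
        n_taus=4,
    ),
}


@dataclass(frozen=True)
class Sequence:
    """A fully timed pulse sequence.

    ``delays`` are center-to-center (ns); ``echo_delay`` is the nominal echo
    time after the last pulse center for the first declared pathway.
    """

    name: str
    pulses: tuple[ChirpPulse, ...]
    phases: tuple[float, ...]
    delays: tuple[float, ...]
    echo_delay: float
    pathways: tuple[CoherencePathway, ...]
    taus: tuple[float, ...]
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for j, gap in enumerate(self.gaps):
            if gap < -1e-9:
                raise ValueError(
                    f"pulses {j + 1} and {j + 2} overlap: center-to-center "
                    f"delay {self.delays[j]} ns < half-length sum "
                    f"{self.delays[j] - gap:.6g} ns"
                )

    @property
    def gaps(self) -> tuple[float, ...]:
        """Free-evolution gaps between pulse edges (ns)."""
        return tuple(
            d - (self.pulses[i].tp + self.pulses[i + 1].tp) / 2.0
            for i, d in enumerate(self.delays)
        )

    @property
    def signs(self) -> tuple[int, ...]:
        return tuple(p.sign for p in self.pulses)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(p.role for p in self.pulses)

    @property
    def lengths(self) -> tuple[float, ...]:
        return tuple(p.tp for p in self.pulses)

    @property
    def total_duration(self) -> float:
        """Sum of all pulse durations and free-evolution gaps (ns)."""
        return sum(p.tp for p in self.pulses) + sum(self.gaps)

    def to_config(self) -> dict:
        return dict(self.params)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_config(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Sequence":
        with open(path) as fh:
            cfg = json.load(fh)
        return make_variant(**cfg)


def make_variant(
    name: str,
    tp_unit: float,
    sw: float,
    *,
    q_pi: float = 5.0,
    taus=(400.0, 400.0),
    n: float = 16.0,
    signs=None,
    carrier_offset: float = 0.0,
) -> Sequence:
    """Build a named sequence template.

    Parameters
    ----------
    name : template name from :data:`TEMPLATES`.
    tp_unit : length of one ratio unit (ns); the 2:2:2:1 SIFTER with
        ``tp_unit=100`` has pulses of 200, 200, 200 and 100 ns.
    sw : common sweep width (MHz).
    q_pi : critical adiabaticity shared by all pi-role pulses; pi/2 pulses
        are always pinned to an exact pi/2 flip.
    taus : the base delays (tau1, tau2[, tau3, tau4]) in ns.
    signs : override the template's sweep directions (some templates' sweep
        directions are assumed, not prescribed).
    """
    if name not in TEMPLATES:
        raise KeyError(
            f"unknown template {name!r}; available: {sorted(TEMPLATES)}"
        )
    tpl = TEMPLATES[name]
    taus = tuple(float(t) for t in np.atleast_1d(taus))
    if len(taus) != tpl.n_taus:
        raise ValueError(f"{name} needs {tpl.n_taus} delay value(s), got {len(taus)}")
    use_signs = tuple(signs) if signs is not None else tpl.signs

    pulses = []
    for ratio, role, sgn in zip(tpl.ratios, tpl.roles, use_signs):
        tp = ratio * tp_unit
        q = PI_HALF_QCRIT if role == "pi/2" else q_pi
        pulses.append(
            ChirpPulse(
                tp=tp, sweep=sw, nu1=amplitude_for_qcrit(q, tp, sw),
                n=n, sign=sgn, carrier_offset=carrier_offset, role=role,
            )
        )
    delays = tuple(
        float(sum(c * t for c, t in zip(row, taus))) for row in tpl.delay_coeffs
    )
    echo = float(sum(c * t for c, t in zip(tpl.echo_coeffs, taus)))
    params = dict(
        name=name, tp_unit=tp_unit, sw=sw, q_pi=q_pi, taus=list(taus),
        n=n, signs=list(use_signs), carrier_offset=carrier_offset,
    )
    return Sequence(
        name=name, pulses=tuple(pulses), phases=tpl.phases, delays=delays,
        echo_delay=echo, pathways=tpl.pathways, taus=taus, params=params,
    )


def make_sifter_2221(
    tp_unit: float, sw: float, tau1: float, tau2: float, *, q_pi: float = 5.0,
    **kw,
) -> Sequence:
    """Standard four-pulse 2:2:2:1 SIFTER: (pi/2)x - (pi)x - (pi/2)y - (pi)x,
    delays tau1, tau1, tau2 and the echo tau2 after the last pulse."""
    return make_variant("sifter_2221", tp_unit, sw, q_pi=q_pi,
                        taus=(tau1, tau2), **kw)


def refocused_train(
    n_pi: int, tp_unit: float, sw: float, *, q_pi: float = 5.0,
    tau: float = 400.0, n: float = 16.0,
) -> Sequence:
    """Refocused-echo train with ``n_pi`` pi pulses and lengths 2:...:2:1.

    All pulses except the last have relative length 2 and the last pi pulse
    has length 1, which refocuses the pi/2 phase roll for any number of pi
    pulses (the alternating-order pathway telescopes).  Delays follow the
    Carr-Purcell pattern tau, 2*tau, ..., 2*tau so the alternating offset
    evolution refocuses tau after the last pulse for any pi count.
    """
    if n_pi < 1:
        raise ValueError("need at least one pi pulse")
    ratios = (2,) * n_pi + (1,)
    orders = [0] + [(-1) ** k for k in range(n_pi + 1)]
    pulses = []
    for i, r in enumerate(ratios):
        role = "pi/2" if i == 0 else "pi"
        tp = r * tp_unit
        q = PI_HALF_QCRIT if role == "pi/2" else q_pi
        pulses.append(
            ChirpPulse(tp=tp, sweep=sw, nu1=amplitude_for_qcrit(q, tp, sw),
                       n=n, sign=1, role=role)
        )
    name = f"refocused_train_{n_pi}pi"
    delays = (tau,) + (2.0 * tau,) * (n_pi - 1)
    return Sequence(
        name=name, pulses=tuple(pulses), phases=(X,) * (n_pi + 1),
        delays=delays, echo_delay=tau,
        pathways=(CoherencePathway.from_orders(orders),),
        taus=(tau,), params=dict(name=name, tp_unit=tp_unit, sw=sw, q_pi=q_pi),
    )


@dataclass(frozen=True)
class SifterSchedule:
    """Per-point delay sets for a 2D dipolar scan.

    ``tau_table`` has one row per 2D point and one column per base delay;
    ``dipolar_time`` is tau2 - tau1 for four-pulse sequences and
    (tau2 + tau3 + tau4) - tau1 for the six-pulse sequence, in ns.
    """

    tau_table: np.ndarray
    dipolar_time: np.ndarray
    dt: float
    mode: str

    @property
    def npoints(self) -> int:
        return self.tau_table.shape[0]


def schedule_2d(
    seq: Sequence, dt: float, npoints: int, mode: str = "tau2_up_tau1_down"
) -> SifterSchedule:
    """Dipolar-time schedule for a SIFTER-type sequence.

    ``dt`` is the increment of the dipolar evolution time per point.  In the
    recommended ``tau2_up_tau1_down`` mode, tau1 decreases while the later
    delays increase, splitting the increment evenly: for the four-pulse
    sequences tau1 -= dt/2 and tau2 += dt/2 per point; for the six-pulse
    sequence tau1 -= dt/2 while tau2, tau3, tau4 each gain dt/6, so all pi
    pulses keep refocusing at every point (pulse lengths never change).
    ``symmetric`` records both signs of the dipolar time around the start.
    """
    if mode not in ("tau2_up_tau1_down", "symmetric"):
        raise ValueError(f"unknown schedule mode {mode!r}")
    taus = np.asarray(seq.taus, dtype=float)
    ntau = taus.size
    if ntau not in (2, 4):
        raise ValueError("2D schedules need a 2- or 4-delay template")
    step = np.zeros(ntau)
    step[0] = -dt / 2.0
    step[1:] = dt / (2.0 * (ntau - 1))

    if mode == "symmetric":
        idx = np.arange(npoints) - (npoints - 1) // 2
    else:
        idx = np.arange(npoints)
    table = taus[None, :] + idx[:, None] * step[None, :]
    dip0 = taus[1:].sum() - taus[0]
    dipolar = dip0 + idx * dt

    # every center-to-center delay must respect the pulse-overlap gaps at
    # every point of the scan
    tpl = TEMPLATES.get(seq.name)
    if tpl is not None:
        coeffs = np.asarray(tpl.delay_coeffs, dtype=float)
        delays = table @ coeffs.T  # (npoints, ngaps)
        half = np.array(
            [
                (seq.pulses[i].tp + seq.pulses[i + 1].tp) / 2.0
                for i in range(len(seq.pulses) - 1)
            ]
        )
        bad_pt, bad_gap = np.where(delays < half[None, :] - 1e-9)
        if bad_pt.size:
            raise ValueError(
                f"delay {bad_gap[0] + 1} under-runs the minimal gap at scan "
                f"point {bad_pt[0]}; at most {int(bad_pt[0])} points are "
                f"feasible with dt={dt} ns"
            )
    if np.any(table < 0):
        raise ValueError("schedule produced a negative delay")
    return SifterSchedule(tau_table=table, dipolar_time=dipolar, dt=dt, mode=mode)
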