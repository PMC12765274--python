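"""Processing of 2D-SIFTER echo data down to distance distributions.

Pipeline: Fourier transform of the broadband echo into the offset spectrum
(with zero-order phasing), optional division by an excitation profile
recorded via field-stepped spectra, per-column background correction
(division by the SIDRE reference trace and by a fitted exponential), a
magnitude FT along the dipolar time axis for the EPR-correlated dipolar
spectrum, and Tikhonov inversion of the orientation-averaged form factor
into a distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .dipolar_sifter import DIPOLAR_CONSTANT_MHZ_NM3, Sifter2D, dipolar_kernel

__all__ = [
    "EchoTransient",
    "ExcitationProfile",
    "DistanceDistribution",
    "echo_ft",
    "excitation_profile_from_field_steps",
    "background_correct",
    "dipolar_ft_2d",
    "tikhonov_distance",
]


@dataclass
class EchoTransient:
    """Uniformly sampled complex echo record (times in ns)."""

    times: np.ndarray
    signal: np.ndarray
    center: float | None = None

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("echo transient must be uniformly sampled")


@dataclass
class ExcitationProfile:
    """Normalized sensitivity of excitation + detection versus offset."""

    offsets: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sensitivity <= 0):
            raise ValueError("sensitivity must be strictly positive")
        self.sensitivity = self.sensitivity / self.sensitivity.max()

    def __call__(self, offsets) -> np.ndarray:
        return np.interp(offsets, self.offsets, self.sensitivity)


@dataclass
class DistanceDistribution:
    """Probability density over a distance grid from Tikhonov inversion."""

    r: np.ndarray                # nm
    density: np.ndarray          # 1/nm, >= 0, integrates to 1
    alpha: float
    residual_norm: float = 0.0
    penalty_norm: float = 0.0

    @property
    def peak(self) -> float:
        return float(self.r[np.argmax(self.density)])

    def to_file(self, path) -> None:
        np.savetxt(path, np.column_stack([self.r, self.density]),
                   header="r_nm probability_density")


def echo_ft(tr: EchoTransient, edge_frac: float = 0.1):
    """FT of the echo into the offset spectrum (offsets MHz, spectrum complex).

    The echo center (located at max |signal| if not supplied) is shifted to
    time zero so the spectrum has no linear phase ramp; the zero-order phase
    is then chosen to maximize the integrated real part.  An echo center
    within ``edge_frac`` of the record edge raises (truncated echo).
    """
    t = tr.times
    s = np.asarray(tr.signal, dtype=complex)
    center = tr.center
    if center is None:
        center = float(t[np.argmax(np.abs(s))])
    span = t[-1] - t[0]
    if center < t[0] + edge_frac * span or center > t[-1] - edge_frac * span:
        raise ValueError(
            f"echo center {center} ns lies within {edge_frac:.0%} of the "
            "record edge; the echo is truncated"
        )
    dt = t[1] - t[0]
    spec = np.fft.fftshift(np.fft.fft(s))
    freqs = np.fft.fftshift(np.fft.fftfreq(t.size, dt * 1e-3))  # MHz
    # shift theorem: reference the FT to the echo center
    spec = spec * np.exp(2j * np.pi * freqs * (center - t[0]) * 1e-3)
    phi = -np.angle(spec.sum())
    return freqs, spec * np.exp(1j * phi)


def excitation_profile_from_field_steps(
    spectra, offsets, shifts, tracked_offset: float = 0.0
) -> ExcitationProfile:
    """Recover the sensitivity profile from field-stepped spectra.

    Stepping the field by ``shift`` moves the spectral feature originally at
    ``tracked_offset`` to ``tracked_offset + shift``; following its
    intensity across the steps traces out the combined
    excitation/refocusing/detection sensitivity at those offsets.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size < 5:
        raise ValueError("need at least 5 field steps to map the profile")
    pos, intens = [], []
    for sh, spec in zip(shifts, spectra):
        p = tracked_offset + sh
        if p < offsets[0] or p > offsets[-1]:
            raise ValueError(
                f"tracked point leaves the recorded band at shift {sh} MHz"
            )
        pos.append(p)
        intens.append(float(np.interp(p, offsets, np.real(spec))))
    pos = np.asarray(pos)
    intens = np.asarray(intens)
    order = np.argsort(pos)
    return ExcitationProfile(offsets=pos[order], sensitivity=intens[order])


def background_correct(
    trace: np.ndarray,
    times: np.ndarray,
    sidre: np.ndarray,
    fit_window: tuple[float, float] = (0.4, 1.0),
):
    """Divide by the SIDRE trace, then by a fitted exponential background.

    The exponential ``A*exp(-k t)`` is fitted log-linearly on the stated
    fraction of the dipolar axis (default: last 60 %), so the corrected
    trace approaches 1 in its tail.  Returns ``(corrected, k_per_us)``.
    Non-positive SIDRE samples raise; a fitted growing background (k < 0)
    is allowed but reported, since it usually signals a bad fit window.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    sidre = np.asarray(sidre, dtype=float)
    if np.any(sidre <= 0):
        raise ValueError("SIDRE trace must be strictly positive for division")
    y = trace / sidre
    t_us = times * 1e-3
    lo = times[0] + fit_window[0] * (times[-1] - times[0])
    hi = times[0] + fit_window[1] * (times[-1] - times[0])
    sel = (times >= lo) & (times <= hi) & (y > 0)
    if sel.sum() < 2:
        raise ValueError("background fit window has fewer than 2 usable points")
    slope, intercept = np.polyfit(t_us[sel], np.log(y[sel]), 1)
    bg = np.exp(intercept + slope * t_us)
    return y / bg, float(-slope)


@dataclass
class DipolarSpectrum2D:
    """EPR-offset x dipolar-frequency correlation spectrum."""

    offsets: np.ndarray          # MHz
    dipolar_freqs: np.ndarray    # MHz, folded (non-negative)
    matrix: np.ndarray           # magnitude FT per offset column
    excluded: np.ndarray         # bool mask of columns below the SNR floor

    def heatmap(self) -> np.ndarray:
        """Each dipolar spectrum normalized and squared, for visual
        tracking of the main dispersion features."""
        m = self.matrix.copy()
        mx = m.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        return (m / mx) ** 2

    def dominant_frequency(self, column: int, f_min: float = 0.0) -> float:
        """Parabolic-refined dominant nonzero dipolar frequency (MHz)."""
        mag = self.matrix[column]
        f = self.dipolar_freqs
        start = max(int(np.searchsorted(f, f_min)), 1)
        k = start + int(np.argmax(mag[start:]))
        if 1 <= k < mag.size - 1:
            y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
            den = y0 - 2 * y1 + y2
            if den != 0:
                return float(f[k] + 0.5 * (y0 - y2) / den * (f[1] - f[0]))
        return float(f[k])


def dipolar_ft_2d(
    ds: Sifter2D,
    sidre: np.ndarray | None = None,
    snr_floor: float = 0.05,
    fit_window: tuple[float, float] = (0.4, 1.0),
) -> DipolarSpectrum2D:
    """Magnitude FT along the dipolar axis of a background-corrected dataset.

    Per offset column: background-correct (SIDRE + exponential division),
    normalize, re-weight by the column's pre-correction t = 0 intensity,
    and magnitude-FT without zero filling or apodization.  Columns whose
    t = 0 intensity falls below ``snr_floor`` of the strongest column are
    excluded (at the spectrum edges the exponential fit is unreliable).
    """
    if sidre is None:
        sidre = ds.sidre
    if sidre is None:
        raise ValueError("a SIDRE reference trace is required")
    spec0 = ds.spectrum
    floor = snr_floor * spec0.max()
    excluded = spec0 < floor
    nt = ds.times.size
    freqs = np.fft.rfftfreq(nt, (ds.times[1] - ds.times[0]) * 1e-3)
    out = np.zeros((ds.offsets.size, freqs.size))
    for i in range(ds.offsets.size):
        if excluded[i]:
            continue
        corr, _ = background_correct(ds.signal[i], ds.times, sidre, fit_window)
        corr = corr - corr.mean()
        peak = np.abs(corr).max()
        if peak > 0:
            corr = corr / peak
        out[i] = np.abs(np.fft.rfft(corr * spec0[i]))
    return DipolarSpectrum2D(
        offsets=ds.offsets, dipolar_freqs=freqs, matrix=out, excluded=excluded
    )


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def _tik_solve(K1, F1, L, alpha):
    A = np.vstack([K1, alpha * np.hstack([L, np.zeros((L.shape[0], 1))])])
    b = np.concatenate([F1, np.zeros(L.shape[0])])
    x, _ = nnls(A, b)
    p = x[:-1]
    res = float(np.linalg.norm(K1 @ x - F1))
    pen = float(np.linalg.norm(L @ p))
    return p, x[-1], res, pen


def tikhonov_distance(
    times: np.ndarray,
    formfactor: np.ndarray,
    r_grid: np.ndarray,
    alpha: float | str = "lcurve",
    *,
    D: float = DIPOLAR_CONSTANT_MHZ_NM3,
    alphas: np.ndarray | None = None,
) -> DistanceDistribution:
    """Non-negative Tikhonov inversion of a dipolar form factor.

    Solves ``min ||K p + c - F||^2 + alpha^2 ||L2 p||^2`` with ``p >= 0``
    (the constant ``c`` absorbs the unmodulated fraction), where
    ``K(t, r)`` is the powder dipolar kernel and ``L2`` the second
    difference.  ``alpha`` may be a number, ``"lcurve"`` (corner of the
    L-curve by maximum curvature, the default) or ``"gcv"``.
    """
    times = np.asarray(times, dtype=float)
    F = np.asarray(formfactor, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    K = dipolar_kernel(times, r_grid, D)
    K1 = np.hstack([K, np.ones((times.size, 1))])
    L = _second_difference(r_grid.size)

    if isinstance(alpha, (int, float)):
        p, c, res, pen = _tik_solve(K1, F, L, float(alpha))
        best_alpha = float(alpha)
    else:
        if alphas is None:
            alphas = np.logspace(-4, 1, 24)
        sols = [_tik_solve(K1, F, L, a) for a in alphas]
        res = np.array([max(s[2], 1e-14) for s in sols])
        pen = np.array([max(s[3], 1e-14) for s in sols])
        if alpha == "lcurve":
            x, y = np.log(res), np.log(pen)
            dx, dy = np.gradient(x), np.gradient(y)
            ddx, ddy = np.gradient(dx), np.gradient(dy)
            denom = (dx**2 + dy**2) ** 1.5
            denom[denom == 0] = np.inf
            curv = (dx * ddy - dy * ddx) / denom
            k = int(np.argmax(curv))
        elif alpha == "gcv":
            # effective dof via the unconstrained influence matrix
            gcv = []
            for a, s in zip(alphas, sols):
                H = K1 @ np.linalg.pinv(
                    K1.T @ K1
                    + a**2
                    * np.block(
                        [[L.T @ L, np.zeros((L.shape[1], 1))],
                         [np.zeros((1, L.shape[1] + 1))]]
                    )
                ) @ K1.T
                tr = times.size - np.trace(H)
                gcv.append(s[2] ** 2 / max(tr, 1e-9) ** 2)
            k = int(np.argmin(gcv))
        else:
            raise ValueError(f"unknown alpha selection {alpha!r}")
        p, c, res, pen = sols[k]
        best_alpha = float(alphas[k])
    if not np.any(p > 0):
        raise ValueError(
            "Tikhonov inversion degenerate: all-zero distribution at every "
            "regularization strength tried"
        )
    area = np.trapezoid(p, r_grid)
    density = p / area if area > 0 else p
    return DistanceDistribution(
        r=r_grid, density=density, alpha=best_alpha,
        residual_norm=float(np.atleast_1d(res)[0] if np.ndim(res) else res),
        penalty_norm=float(np.atleast_1d(pen)[0] if np.ndim(pen) else pen),
    )
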