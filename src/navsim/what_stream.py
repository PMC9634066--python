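"""Frequency-coded landmark recognition with a bank of Van-der-Pol units.

Each stored landmark is represented by a neuronal ensemble modelled as a
driven Van-der-Pol oscillator

    dX/dt = (lambda - Y^2) X - P^2 Y + B * As * sin(omega_s t)
    dY/dt = X

where Y is the ensemble output, P its natural (angular) frequency, lambda the
bifurcation parameter and ``B * As * sin(omega_s t)`` the sinusoidal stimulus
emitted by an encountered landmark (amplitude As, frequency omega_s equal to
the landmark's identification code).  For lambda < 0 the unit is quiescent;
for 0 < lambda <= 1 it sustains a near-sinusoidal limit cycle of amplitude
2*sqrt(lambda) at frequency ~P.  A landmark is recognised by adaptive
resonance: the unit whose tuning matches the stimulus frequency is driven
above the unity amplitude threshold while remaining frequency-locked to the
input; mismatched units stay below threshold.

Raising lambda produces relaxation oscillations: the dominant frequency drops
below P and spectral power shifts into low frequencies, emulating the EEG
slowing observed in Alzheimer's disease.  At lambda = 15.2 every unit
oscillates with large amplitude at its own slowed frequency regardless of the
stimulus, so no unit responds specifically and recognition fails.

All spectra are reported on the angular-frequency ("code unit") axis, on
which a unit with parameter P peaks at frequency value P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import hilbert, welch

__all__ = [
    "VdpUnit",
    "Stimulus",
    "UnitResponse",
    "simulate_unit",
    "default_bank",
    "bank_response",
    "recognize_landmark",
    "spectral_summary",
]

log = logging.getLogger(__name__)

#: Healthy and Alzheimer's-disease values of the bifurcation parameter.
LAMBDA_HEALTHY = 0.2
LAMBDA_AD = 15.2

#: Default integration window and step (code units of time).
T_END_DEFAULT = 80.0
DT_DEFAULT = 0.005
TRANSIENT_FRACTION = 0.3

#: Fraction of the post-transient window (taken from its end) over which the
#: steady-state envelope statistic is computed.
_STEADY_FRACTION = 0.5

#: Band split for low/high spectral power, code units.
BAND_SPLIT_DEFAULT = 3.0


@dataclass
class VdpUnit:
    """One Van-der-Pol neuronal ensemble tuned to natural frequency P."""

    P: float
    lam: float = LAMBDA_HEALTHY
    B: float = 1.5
    state: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.P <= 0:
            raise ValueError(f"natural frequency P must be positive, got {self.P}")


@dataclass
class Stimulus:
    """Sinusoidal landmark stimulus: amplitude As at frequency omega_s."""

    omega_s: float
    As: float = 1.0
    onset: float = 0.0
    duration: float = float("inf")

    def __post_init__(self) -> None:
        if self.As < 0:
            raise ValueError("stimulus amplitude As must be >= 0")
        if self.omega_s <= 0:
            raise ValueError("stimulus frequency omega_s must be positive")


@dataclass
class UnitResponse:
    """Trajectory plus envelope and spectral summaries of one simulated unit."""

    t: np.ndarray
    y: np.ndarray
    envelope: np.ndarray
    psd_freq: np.ndarray          # code-unit (angular) frequency axis
    psd_power: np.ndarray
    dominant_freq: float
    peak_envelope: float          # steady-state envelope amplitude (late-window median)
    P: float
    lam: float
    omega_s: float | None = None
    transient_index: int = 0

    @property
    def psd(self) -> np.ndarray:
        return np.column_stack([self.psd_freq, self.psd_power])


def _dominant_frequency(y: np.ndarray, dt: float) -> float:
    """Dominant angular frequency via Hann-windowed, zero-padded rFFT with
    parabolic interpolation of the spectral peak (sub-bin accuracy)."""
    n = len(y)
    w = np.hanning(n)
    nfft = 8 * 2 ** int(np.ceil(np.log2(n)))
    spec = np.abs(np.fft.rfft((y - y.mean()) * w, nfft))
    f = np.fft.rfftfreq(nfft, dt)
    k = int(np.argmax(spec[1:]) + 1)
    if 1 <= k < len(spec) - 1:
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return float(2 * np.pi * (f[k] + delta * (f[1] - f[0])))


def simulate_unit(
    unit: VdpUnit,
    stim: Stimulus | None = None,
    t_end: float = T_END_DEFAULT,
    dt: float = DT_DEFAULT,
    method: str = "RK45",
) -> UnitResponse:
    """Integrate one unit and summarise its response.

    Initial state is (0, 0) for driven runs (the stimulus seeds the motion)
    and (0.1, 0) for unforced runs (a limit cycle needs a nonzero seed),
    unless ``unit.state`` is nonzero, in which case it is used as-is.
    The step guard requires ``dt * max(P, omega_s) <= 0.1``.

    ``method`` is "RK45" (adaptive, default) or "rk4" (fixed-step fallback).
    """
    driven = stim is not None and stim.As > 0
    fmax = max(unit.P, stim.omega_s) if driven else unit.P
    if dt * fmax > 0.1:
        raise ValueError(
            f"dt={dt} too coarse for max frequency {fmax}: need dt*f <= 0.1"
        )

    if unit.state != (0.0, 0.0):
        y0 = list(unit.state)
    else:
        y0 = [0.0, 0.0] if driven else [0.1, 0.0]

    lam, P2, = unit.lam, unit.P**2
    if driven:
        amp, ws, on, off = (
            unit.B * stim.As,
            stim.omega_s,
            stim.onset,
            stim.onset + stim.duration,
        )

        def rhs(t, s):
            x, y = s
            d = amp * np.sin(ws * (t - on)) if on <= t < off else 0.0
            return ((lam - y * y) * x - P2 * y + d, x)

    else:

        def rhs(t, s):
            x, y = s
            return ((lam - y * y) * x - P2 * y, x)

    t = np.arange(0.0, t_end, dt)
    if method.upper() == "RK45":
        sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=t, method="RK45",
                        rtol=1e-8, atol=1e-10)
        y = sol.y[1]
        if not sol.success or not np.all(np.isfinite(y)):
            raise RuntimeError(
                f"integration blew up (lam={unit.lam}, dt={dt}); state non-finite"
            )
    elif method.lower() == "rk4":
        y = _rk4(rhs, y0, t, dt)
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(y)):
        raise RuntimeError(
            f"integration blew up (lam={unit.lam}, dt={dt}); state non-finite"
        )

    i0 = int(TRANSIENT_FRACTION * len(t))
    env = np.abs(hilbert(y))
    post = y[i0:]
    steady_start = len(env) - int(_STEADY_FRACTION * (len(env) - i0))
    peak = float(np.median(env[steady_start:]))

    nper = min(len(post), 4096)
    f_hz, pxx = welch(post, fs=1.0 / dt, nperseg=nper)
    dom = _dominant_frequency(post, dt)

    return UnitResponse(
        t=t,
        y=y,
        envelope=env,
        psd_freq=2 * np.pi * f_hz,
        psd_power=pxx,
        dominant_freq=dom,
        peak_envelope=peak,
        P=unit.P,
        lam=unit.lam,
        omega_s=stim.omega_s if stim is not None else None,
        transient_index=i0,
    )


def _rk4(rhs, y0, t, dt):
    s = np.array(y0, dtype=float)
    out = np.empty(len(t))
    out[0] = s[1]
    for i in range(1, len(t)):
        ti = t[i - 1]
        k1 = np.asarray(rhs(ti, s))
        k2 = np.asarray(rhs(ti + dt / 2, s + dt / 2 * k1))
        k3 = np.asarray(rhs(ti + dt / 2, s + dt / 2 * k2))
        k4 = np.asarray(rhs(ti + dt, s + dt * k3))
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = s[1]
    return out


def default_bank(
    lam: float = LAMBDA_HEALTHY,
    codes=(4, 5, 6, 7, 8, 9),
    B: float = 1.5,
) -> list[VdpUnit]:
    """Six units tuned to the route landmark codes (P = 4..9 by default)."""
    return [VdpUnit(P=float(c), lam=lam, B=B) for c in codes]


def bank_response(
    bank: list[VdpUnit],
    landmark,
    t_end: float = T_END_DEFAULT,
    dt: float = DT_DEFAULT,
    As: float = 1.0,
) -> list[UnitResponse]:
    """Drive every unit in the bank with the landmark's stimulus.

    ``landmark`` may be a ``cogmap.Landmark`` or a bare frequency code.
    """
    if not bank:
        raise ValueError("oscillator bank is empty")
    code = float(getattr(landmark, "freq_code", landmark))
    stim = Stimulus(omega_s=code, As=As) if As > 0 else None
    return [simulate_unit(u, stim, t_end=t_end, dt=dt) for u in bank]


def recognize_landmark(
    responses: list[UnitResponse],
    threshold: float = 1.0,
    freq_rtol: float | None = 0.05,
) -> int | None:
    """Index of the unit that recognises the common drive, or ``None``.

    A unit qualifies when its steady-state envelope crosses ``threshold`` and
    (adaptive resonance) its dominant response frequency matches both the
    drive frequency and the unit's own tuning P within ``freq_rtol``.  Pass
    ``freq_rtol=None`` for the bare threshold criterion.  If several units
    qualify the one with the largest envelope wins (tie -> lowest index,
    logged).
    """
    qualifying: list[int] = []
    for i, r in enumerate(responses):
        if r.peak_envelope < threshold:
            continue
        if freq_rtol is not None:
            ws = r.omega_s
            if ws is None:
                continue
            if abs(r.dominant_freq - ws) > freq_rtol * ws:
                continue
            if abs(r.dominant_freq - r.P) > freq_rtol * r.P:
                continue
        qualifying.append(i)
    if not qualifying:
        return None
    best = max(qualifying, key=lambda i: responses[i].peak_envelope)
    peaks = [responses[i].peak_envelope for i in qualifying]
    if len(qualifying) > 1:
        if peaks.count(max(peaks)) > 1:
            best = min(i for i in qualifying if responses[i].peak_envelope == max(peaks))
            log.warning("recognition tie between units %s; keeping index %d",
                        qualifying, best)
        else:
            log.info("multiple units crossed threshold %s; keeping largest peak", qualifying)
    return best


def spectral_summary(
    resp: UnitResponse,
    split: float = BAND_SPLIT_DEFAULT,
) -> tuple[float, float, float]:
    """(dominant_freq, low_band_power, high_band_power) on the code-unit axis.

    Band powers integrate the Welch PSD below/above ``split``.  Requires the
    post-transient window to contain at least 20 cycles of the slower of
    (P, omega_s).
    """
    t_post = resp.t[-1] - resp.t[resp.transient_index]
    slow = min(resp.P, resp.omega_s) if resp.omega_s else resp.P
    cycles = t_post * slow / (2 * np.pi)
    if cycles < 20:
        raise ValueError(
            f"post-transient window holds only {cycles:.1f} cycles of the slower "
            f"frequency {slow}; need >= 20"
        )
    f, p = resp.psd_freq, resp.psd_power
    low = float(np.trapezoid(p[f < split], f[f < split])) if np.any(f < split) else 0.0
    high = float(np.trapezoid(p[f >= split], f[f >= split])) if np.any(f >= split) else 0.0
    return resp.dominant_freq, low, high
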