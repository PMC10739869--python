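"""Time-domain simulation of a dispersive sample under uniform-field conditions.

A plate-electrode sample with a multipole Debye dispersion carries the
current density

    J(t) = sigma_s E(t) + eps0 eps_inf dE/dt + sum_k J_ek(t)
    J_ek(t) = (eps0 d_eps_k / tau_k) (E(t) - e_k(t))
    tau_k de_k/dt = E(t) - e_k(t)

where each auxiliary field ``e_k`` is a first-order low-pass copy of the
electric field — the auxiliary-differential-equation (ADE) form of the
dispersion.  Under uniform-field (lumped) conditions E(t) = V(t)/l and the
terminal current is I(t) = S * J(t).

The auxiliary ODEs are integrated with an adaptive implicit (BDF) solver;
the per-pole time constants span four decades for the tissue models here, so
stiffness is the norm.  Sources provide an analytic time derivative so that
the eps_inf displacement term never relies on numerical differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .dispersion import EPS0, DebyeMultipole, SampleGeometry


class SourceError(ValueError):
    pass


@dataclass(frozen=True)
class SourceSignal:
    """Applied voltage waveform with analytic derivative.

    Use the constructors :meth:`sine`, :meth:`pulse_burst` or
    :meth:`custom`.  ``value`` and ``derivative`` are vectorised callables
    of time (s) returning volts and volts/second.
    """

    kind: str
    value: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    amplitude: float
    #: solver restart points (waveform derivative breaks); always includes 0
    breakpoints: tuple[float, ...] = ()
    #: max-step ceiling between consecutive breakpoints; scalar fallback
    max_steps: tuple[float, ...] = ()
    default_duration: float | None = None
    frequency: float | None = None

    @classmethod
    def sine(cls, frequency: float, amplitude: float = 50.0,
             periods: float = 5.0) -> "SourceSignal":
        """V(t) = A sin(2 pi f t); default max step one hundredth of a period."""
        if frequency <= 0:
            raise SourceError("frequency must be > 0")
        w = 2.0 * np.pi * frequency
        period = 1.0 / frequency
        return cls(
            kind="sine",
            value=lambda t: amplitude * np.sin(w * np.asarray(t, float)),
            derivative=lambda t: amplitude * w * np.cos(w * np.asarray(t, float)),
            amplitude=amplitude,
            breakpoints=(0.0,),
            max_steps=(period / 100.0,),
            default_duration=periods * period,
            frequency=frequency,
        )

    @classmethod
    def pulse_burst(cls, n_pulses: int = 4, width: float = 100e-6,
                    period: float = 200e-6, amplitude: float = 50.0,
                    transition: float = 8e-6) -> "SourceSignal":
        """Trapezoidal pulse burst (electroporation-style PEF protocol).

        Each pulse is ``width`` long with linear rise/fall edges of length
        ``transition`` inside it, repeating every ``period``.  Defaults: four
        100 us pulses at 50 V every 200 us with 8 us edges.  The max-step
        policy is 0.1 us inside edges and 1 us elsewhere.
        """
        if not (0 < 2 * transition <= width <= period):
            raise SourceError("require 0 < 2*transition <= width <= period")

        def value(t):
            t = np.asarray(t, float)
            i = np.floor(t / period)
            tl = t - i * period
            in_burst = (i >= 0) & (i < n_pulses)
            rise = np.clip(tl / transition, 0.0, 1.0)
            fall = np.clip((width - tl) / transition, 0.0, 1.0)
            return amplitude * in_burst * np.minimum(rise, fall) * (tl < width)

        def derivative(t):
            t = np.asarray(t, float)
            i = np.floor(t / period)
            tl = t - i * period
            in_burst = (i >= 0) & (i < n_pulses)
            up = (tl >= 0) & (tl < transition)
            down = (tl > width - transition) & (tl < width)
            return amplitude / transition * in_burst * (
                up.astype(float) - down.astype(float))

        bp, ms = [], []
        for i in range(n_pulses):
            t0 = i * period
            # edge, plateau, edge, gap
            bp += [t0, t0 + transition, t0 + width - transition, t0 + width]
            ms += [0.1e-6, 1e-6, 0.1e-6, 1e-6]
        return cls(
            kind="pulse_burst",
            value=value,
            derivative=derivative,
            amplitude=amplitude,
            breakpoints=tuple(bp),
            max_steps=tuple(ms),
            default_duration=n_pulses * period,
        )

    @classmethod
    def custom(cls, value, derivative, amplitude: float,
               max_step: float, duration: float | None = None) -> "SourceSignal":
        if derivative is None:
            raise SourceError("custom sources must supply an analytic derivative")
        return cls(kind="custom", value=value, derivative=derivative,
                   amplitude=amplitude, breakpoints=(0.0,),
                   max_steps=(max_step,), default_duration=duration)

    def segments(self, t_end: float):
        """(t0, t1, max_step) solver segments covering [0, t_end]."""
        bp = [b for b in self.breakpoints if 0.0 <= b < t_end]
        if not bp or bp[0] > 0.0:
            bp = [0.0] + bp
        edges = bp + [t_end]
        out = []
        for i in range(len(edges) - 1):
            ms = self.max_steps[min(i, len(self.max_steps) - 1)]
            if edges[i + 1] > edges[i]:
                out.append((edges[i], edges[i + 1], ms))
        return out


@dataclass(frozen=True)
class TimeSimResult:
    """Terminal current trace with the applied voltage and solver metadata."""

    t: np.ndarray
    current: np.ndarray
    voltage: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (len(t) == len(self.current) == len(self.voltage)):
            raise ValueError("t, current, voltage must have equal length")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
        ax[0].plot(self.t * 1e3, self.voltage)
        ax[0].set_ylabel("V (V)")
        ax[1].plot(self.t * 1e3, self.current)
        ax[1].set(xlabel="t (ms)", ylabel="I (A)")
        return ax

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t_s": self.t, "V_V": self.voltage, "I_A": self.current})


def _current_from_state(model: DebyeMultipole, geometry: SampleGeometry,
                        E, dEdt, e_states) -> np.ndarray:
    """I = S [ sigma_s E + eps0 eps_inf dE/dt + sum_k c_k (E - e_k) ]."""
    J = model.sigma_s * E + EPS0 * model.eps_inf * dEdt
    for k, p in enumerate(model.poles):
        J = J + (EPS0 * p.delta_eps / p.tau) * (E - e_states[k])
    return geometry.area * J


def simulate_lumped(model: DebyeMultipole, geometry: SampleGeometry,
                    source: SourceSignal, t_end: float | None = None,
                    max_step_scale: float = 1.0,
                    points_per_segment_step: int = 2,
                    rtol: float = 1e-10) -> TimeSimResult:
    """Integrate the lumped ADE system and return the terminal current.

    The source's max-step policy is honoured per segment (scaled by
    ``max_step_scale``, e.g. 0.5 to halve every step ceiling for a
    convergence check); the solver restarts at waveform breakpoints so edge
    discontinuities in dV/dt are never stepped across.  Initial auxiliary
    fields are zero.
    """
    if model.is_cole_cole:
        raise SourceError("time-domain simulation requires first-order (Debye) poles")
    t_end = t_end if t_end is not None else source.default_duration
    if t_end is None or t_end <= 0:
        raise SourceError("t_end required for sources without a default duration")

    length = geometry.length
    taus = np.array([p.tau for p in model.poles])
    E_scale = max(source.amplitude, 1e-30) / length

    def rhs(t, y):
        return (source.value(t) / length - y) / taus

    def jac(t, y):
        return np.diag(-1.0 / taus)

    t_all, y_all = [], []
    y0 = np.zeros(len(taus))
    n_steps = 0
    for (t0, t1, ms) in source.segments(t_end):
        ms = ms * max_step_scale
        n_eval = max(int(np.ceil((t1 - t0) / ms)) * points_per_segment_step, 2)
        t_eval = np.linspace(t0, t1, n_eval + 1)
        if len(taus):
            sol = solve_ivp(rhs, (t0, t1), y0, method="BDF", jac=jac,
                            max_step=ms, rtol=rtol, atol=1e-8 * E_scale,
                            t_eval=t_eval)
            if not sol.success:
                raise RuntimeError(
                    f"stiff-solver failure in [{t0:g},{t1:g}]: {sol.message}; "
                    f"try a smaller max step than {ms:g} s")
            y0 = sol.y[:, -1]
            ys = sol.y
            n_steps += sol.t.size
        else:
            ys = np.zeros((0, t_eval.size))
        if t_all:  # drop duplicated segment joint
            t_all.append(t_eval[1:])
            y_all.append(ys[:, 1:])
        else:
            t_all.append(t_eval)
            y_all.append(ys)
    t = np.concatenate(t_all)
    e_states = np.concatenate(y_all, axis=1)
    E = source.value(t) / length
    dEdt = source.derivative(t) / length
    current = _current_from_state(model, geometry, E, dEdt, e_states)
    V = source.value(t)
    return TimeSimResult(t, current, np.asarray(V, float),
                         meta={"solver": "BDF", "steps": n_steps,
                               "max_step_scale": max_step_scale})


def simulate_static_conductivity(sigma_s: float, geometry: SampleGeometry,
                                 source: SourceSignal,
                                 t_end: float | None = None,
                                 points: int = 4000) -> TimeSimResult:
    """Purely resistive comparator: I(t) = S sigma_s V(t) / l.

    This is the 'no dispersion' model: the waveform is an exact scalar
    multiple of the applied voltage, so pulse plateaus are flat, unlike the
    intra-pulse droop a dispersive sample shows.
    """
    t_end = t_end if t_end is not None else source.default_duration
    if t_end is None or t_end <= 0:
        raise SourceError("t_end required for sources without a default duration")
    # sample on the segment grid so edges are resolved
    ts = [np.linspace(t0, t1, max(int(np.ceil((t1 - t0) / ms)), 2) + 1)
          for (t0, t1, ms) in source.segments(t_end)]
    t = np.unique(np.concatenate(ts))
    V = np.asarray(source.value(t), float)
    I = sigma_s * (geometry.area / geometry.length) * V
    return TimeSimResult(t, I, V, meta={"solver": "algebraic"})


def extract_amplitude_phase(result: TimeSimResult, freq: float,
                            window: float = 1.0) -> tuple[float, float]:
    """Amplitude (A) and phase lead (degrees) of the steady-state current.

    Fits ``a cos(wt) + b sin(wt) + c`` by least squares to the final
    ``window`` periods of both the current and the voltage; the returned
    phase is the current's phase minus the voltage's, i.e. the lead of the
    current (positive for a capacitive sample).
    """
    w = 2.0 * np.pi * freq
    t_start = result.t[-1] - window / freq
    if t_start < result.t[0] - 1e-12 / freq:
        raise ValueError("window exceeds the simulated span")
    m = result.t >= t_start - 1e-15
    t = result.t[m]
    A = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])

    def _fit(y):
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b, _c = coef
        return np.hypot(a, b), np.arctan2(a, b)

    amp_i, ph_i = _fit(result.current[m])
    amp_v, ph_v = _fit(result.voltage[m])
    lead = np.degrees(np.angle(np.exp(1j * (ph_i - ph_v))))
    return float(amp_i), float(lead)
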