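"""Three-element Windkessel outlet model.

The downstream vasculature is lumped into a proximal (characteristic)
impedance ``Rc``, a peripheral resistance ``Rp`` and a compliance ``Cw``.
With flow rate Q(t) entering the element, the outlet pressure obeys

    P = Q (Rp + Rc) + Cw Rp Rc dQ/dt - Cw Rp dP/dt.

For a two-dimensional simulation Q is a flow rate per unit depth [m^2/s] and
the resistances carry the matching units; the model is linear so only the
products matter.  The default parameters were fitted with
:func:`fit_windkessel` against a synthetic 120/80 mmHg pressure trace driven
by the default inlet waveform through a 20 mm bore (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["WindkesselParams", "windkessel_pressure", "fit_windkessel",
           "WindkesselFitResult"]


@dataclass(frozen=True)
class WindkesselParams:
    """Lumped-parameter outlet: all three elements strictly positive.

    Defaults are a least-squares fit of the model pressure to a synthetic
    physiological (120/80 mmHg) waveform for the default pulsatile inflow
    through a 20 mm x 1 m section (Q in m^2/s, R in Pa s/m^2, C in m^2/Pa).
    """

    Rc: float = 1.8123e5
    Rp: float = 5.8953e6
    Cw: float = 3.6244e-7

    def __post_init__(self):
        if min(self.Rc, self.Rp, self.Cw) <= 0:
            raise ValueError("Windkessel parameters must be positive")


def windkessel_pressure(Q, params: WindkesselParams, dt: float,
                        P0: float = None) -> np.ndarray:
    """Integrate the outlet-pressure ODE for a sampled flow trace.

    Uses the trapezoidal rule (second order), so a sinusoidal Q reproduces
    the analytic transfer function of the linear ODE to O(dt^2).  A constant
    Q settles exactly on P = Q (Rp + Rc).  ``P0`` defaults to the steady
    pressure of the first sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    Q = np.asarray(Q, dtype=float)
    Rc, Rp, Cw = params.Rc, params.Rp, params.Cw
    tau = Cw * Rp
    dQdt = np.gradient(Q, dt)
    F = Q * (Rp + Rc) + Cw * Rp * Rc * dQdt     # forcing; dP/dt = (F - P)/tau
    P = np.empty_like(Q)
    P[0] = Q[0] * (Rp + Rc) if P0 is None else P0
    a = dt / (2.0 * tau)
    for i in range(1, Q.size):
        P[i] = ((1.0 - a) * P[i - 1] + a * (F[i] + F[i - 1])) / (1.0 + a)
    return P


class WindkesselStepper:
    """Stateful one-step integrator for use inside a time loop."""

    def __init__(self, params: WindkesselParams, dt: float, P0: float = 0.0,
                 Q0: float = 0.0):
        self.p = params
        self.dt = dt
        self.P = P0
        self._Q_prev = Q0
        self._F_prev = Q0 * (params.Rp + params.Rc)

    def step(self, Q: float) -> float:
        p = self.p
        dQdt = (Q - self._Q_prev) / self.dt
        F = Q * (p.Rp + p.Rc) + p.Cw * p.Rp * p.Rc * dQdt
        a = self.dt / (2.0 * p.Cw * p.Rp)
        self.P = ((1.0 - a) * self.P + a * (F + self._F_prev)) / (1.0 + a)
        self._Q_prev, self._F_prev = Q, F
        return self.P


@dataclass
class WindkesselFitResult:
    params: WindkesselParams
    residual: float               # RMS pressure mismatch, Pa
    identifiable: bool


def fit_windkessel(Q, P_target, dt: float, n_transient: int = None,
                   x0=(1e5, 1e6, 1e-6)) -> WindkesselFitResult:
    """Least-squares fit of (Rc, Rp, Cw) to a target pressure trace.

    Both traces must be uniformly sampled and cover at least one full cycle
    of the driving flow.  The initial transient (default: the first quarter
    of the trace) is excluded from the residual.  Degenerate traces (constant
    Q and P) only constrain the sum Rp+Rc; the fit is then flagged
    ``identifiable=False``.
    """
    Q = np.asarray(Q, dtype=float)
    P_target = np.asarray(P_target, dtype=float)
    if Q.shape != P_target.shape or Q.ndim != 1:
        raise ValueError("Q and P_target must be 1-D traces of equal length")
    if Q.size < 8:
        raise ValueError("traces too short to fit a Windkessel model")
    if n_transient is None:
        n_transient = Q.size // 4
    scale = max(np.abs(P_target).max(), 1.0)

    degenerate = np.ptp(Q) < 1e-12 * max(np.abs(Q).max(), 1.0)

    def resid(logx):
        Rc, Rp, Cw = np.exp(logx)
        P = windkessel_pressure(Q, WindkesselParams(Rc, Rp, Cw), dt,
                                P0=P_target[0])
        return (P[n_transient:] - P_target[n_transient:]) / scale

    sol = least_squares(resid, np.log(np.asarray(x0, dtype=float)),
                        method="lm", xtol=1e-14, ftol=1e-14)
    Rc, Rp, Cw = np.exp(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)) * scale)
    return WindkesselFitResult(WindkesselParams(Rc, Rp, Cw), rms,
                               identifiable=not degenerate)
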