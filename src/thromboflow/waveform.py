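"""Pulsatile inlet waveform.

The aortic inflow is a parametric waveform at 1.02 Hz with a 0.51 m/s peak:
a systolic half-sine, a brief reverse-flow notch at end systole, and a low
constant diastolic flow.  The profile is flat (plug) across the inlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InletWaveform", "inlet_velocity", "bfs_inlet_velocity"]


@dataclass(frozen=True)
class InletWaveform:
    """Parametric aortic inflow: systole + reverse notch + diastolic base.

    ``systole_fraction`` and ``reverse_fraction`` are fractions of the cycle
    period; the shape parameters are adjustable, the frequency/peak defaults
    are the stated physiological values.
    """

    frequency: float = 1.02           # Hz
    peak_velocity: float = 0.51       # m/s
    systole_fraction: float = 0.34
    reverse_fraction: float = 0.12
    reverse_peak: float = 0.08        # m/s, magnitude of the reverse notch
    diastolic_velocity: float = 0.01  # m/s

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def inlet_velocity(t, w: InletWaveform = InletWaveform()):
    """Plug inlet velocity [m/s] at time(s) ``t``; periodic in ``w.period``.

    The maximum over one period equals ``w.peak_velocity`` (attained at
    mid-systole).
    """
    t = np.asarray(t, dtype=float)
    tau = np.mod(t, w.period) / w.period        # cycle phase in [0, 1)
    ts, tr = w.systole_fraction, w.reverse_fraction
    u = np.full_like(tau, w.diastolic_velocity)
    sys = tau < ts
    u = np.where(sys, w.peak_velocity * np.sin(np.pi * tau / ts), u)
    rev = (~sys) & (tau < ts + tr)
    u = np.where(rev, -w.reverse_peak * np.sin(np.pi * (tau - ts) / tr), u)
    return u if u.shape else float(u)


def bfs_inlet_velocity(flow_rate_lpm: float, grid) -> float:
    """Steady plug velocity [m/s] for a volumetric inflow in L/min.

    The inlet cross-section is taken from the grid: ``pi r^2`` for the
    axisymmetric tube, ``height * unit depth`` for a planar channel.
    """
    q = flow_rate_lpm * 1e-3 / 60.0             # m^3/s
    inlet_rows = grid.jj[grid.inlet_cells]
    if grid.axisymmetric:
        r = (inlet_rows.max() + 1) * grid.dy
        area = np.pi * r * r
    else:
        area = inlet_rows.size * grid.dy        # per metre depth
    return q / area
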