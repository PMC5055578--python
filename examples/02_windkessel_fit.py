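"""Fitting the three-element Windkessel outlet to a physiological pressure.

Reproduces how the package's default outlet parameters were obtained: the
default pulsatile inflow through a 20 mm bore drives the lumped model, and
(Rc, Rp, Cw) are fitted so the predicted outlet pressure matches a
synthetic 120/80 mmHg trace.
"""

import numpy as np

from thromboflow import (InletWaveform, fit_windkessel, inlet_velocity,
                         windkessel_pressure)

MMHG = 133.322
w = InletWaveform()
dt = 1e-3
t = np.arange(0.0, 6 * w.period, dt)
Q = inlet_velocity(t, w) * 0.02               # flow per unit depth, m^2/s

# synthetic target: systolic rise to ~120 mmHg, diastolic decay to 80
tau = np.mod(t, w.period) / w.period
P = np.empty_like(t)
rise = tau < 0.3
P[rise] = 85 + 35 * np.sin(np.pi * tau[rise] / 0.6)
P[~rise] = 80 + 40 * np.exp(-(tau[~rise] - 0.3) / 0.35)
P *= MMHG

fit = fit_windkessel(Q, P, dt, n_transient=int(2 * w.period / dt))
print(f"fitted Rc = {fit.params.Rc:.4g} Pa s/m^2")
print(f"fitted Rp = {fit.params.Rp:.4g} Pa s/m^2")
print(f"fitted Cw = {fit.params.Cw:.4g} m^2/Pa")
print(f"RMS mismatch: {fit.residual/MMHG:.2f} mmHg")

Pm = windkessel_pressure(Q, fit.params, dt, P0=P[0])
late = slice(int(4 * w.period / dt), None)
print(f"model pressure range: {Pm[late].min()/MMHG:.1f} / "
      f"{Pm[late].max()/MMHG:.1f} mmHg (target 80/120)")
print("-> these values are the package defaults for the phantom outlet;")
print("   with rigid walls they shift the pressure gauge but not velocity")
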