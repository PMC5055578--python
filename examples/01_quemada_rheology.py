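"""Quemada shear-thinning viscosity of blood.

Evaluates the viscosity curve at 45 % and 30 % hematocrit and the clot
viscosity amplification, and prints the shear stress at the platelet
activation shear rate of 10,000 1/s (calibrated to ~40 Pa).
"""

import numpy as np

from thromboflow import RheologyParams, effective_viscosity, quemada_viscosity

p45 = RheologyParams()                  # 45 % hematocrit (phantom runs)
p30 = RheologyParams(hematocrit=0.30)   # 30 % hematocrit (step benchmark)

print("shear rate [1/s]   mu(45%) [mPa s]   mu(30%) [mPa s]")
for g in [1, 10, 100, 1000, 10000]:
    print(f"{g:>14}   {1e3*quemada_viscosity(g, p45):15.3f}"
          f"   {1e3*quemada_viscosity(g, p30):15.3f}")

tau = float(quemada_viscosity(1e4, p45)) * 1e4
print(f"\nstress at the activation shear rate (10,000 1/s): {tau:.1f} Pa")
print("-> a cell crossing a tear jet above this shear is considered "
      "activation-prone")

mu0 = float(quemada_viscosity(100.0, p45))
for bp in [0.0, 10.0, 20.0, 100.0]:
    amp = float(effective_viscosity(mu0, bp, p45)) / mu0
    print(f"bound platelets {bp:5.0f} nmol/L -> viscosity x{amp:6.1f}")
print("-> inside a clot (BP >> 20 nmol/L) blood is ~100x more viscous")
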