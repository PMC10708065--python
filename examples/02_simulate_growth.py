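"""Simulate 200 h of polycondensation at the fitted rate constants.

Integrates the condensed three-variable model with the auto-adaptive Euler
scheme (1 s base step) and compares the predicted number-average molecular
weight with the four GPC readings of the optimal run.  Note the shape:
after a fast initial drop to the quasi-equilibrium oligomer plateau, Mn
grows slowly while water is still abundant, then almost linearly once the
azeotropic loop has stripped the water out.
"""

import numpy as np

import placond as pc

init = pc.initial_concentrations(pc.reference_ledger(), 7.11)
params = pc.KineticParameters(k1=15.06, k_neg1=6.47e-2, kw=4.85e-4)

hours = np.arange(1.0, 201.0)
traj = pc.simulate(params, init, sample_times=hours * 3600.0)
print(f"stable run: {traj.stable}, {traj.n_steps} Euler steps")

gpc = pc.reference_dataset()
print("\n   time    model Mn    measured Mn")
for t_h, mn_obs in zip(gpc.time_h, gpc.mn):
    mn_model = traj.mn[int(round(t_h)) - 1]
    print(f"  {t_h:5.1f} h  {mn_model:9.0f}    {mn_obs:9.0f}  Da")

k = np.searchsorted(hours, 40.0)
print(f"\nwater at 40 h: {traj.w[k]:.3f} mol/L; at 200 h: {traj.w[-1]:.2e} mol/L")
print("Model overestimates the slow-growth period and matches the late,")
print("water-starved linear regime - the removal term drives the kinetics.")
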