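"""Resolve the full chain-length distribution and check the condensed model.

The chain-resolved population balance tracks every degree of
polymerization up to a truncation ceiling.  It is the only route to
weight-average molecular weights and dispersity, and summing it must
reproduce the condensed three-variable model - verified here on a closed
system (no water removal) where the equivalence is exact up to truncation.
"""

import numpy as np

import placond as pc

params = pc.KineticParameters(k1=0.5, k_neg1=0.02, kw=0.0)  # keq = 25
state0 = pc.monomer_initial_state(a0=2.0, w0=1e-4, S=9.4, C=0.007, n_max=256)
settings = pc.IntegratorSettings(base_step=0.1, t_end=2000.0)
times = np.array([10.0, 100.0, 2000.0])

resolved = pc.simulate_chain(params, state0, settings, times)
print(f"resolved run stable: {resolved.stable}, "
      f"truncation leak {resolved.leak_ratio:.1e} (flagged: {resolved.leak_flagged})")

for k, t in enumerate(times):
    mn, mw, d = pc.distribution_moments(resolved.state_at(k))
    print(f"  t = {t:6.0f} s   Mn = {mn:6.1f}  Mw = {mw:6.1f}  dispersity = {d:.3f}")

init = pc.InitialState(a0=2.0, c0=0.0, w0=1e-4, S=9.4, C=0.007)
condensed = pc.simulate(params, init, settings, times)
agg = pc.aggregate(resolved.state_at(-1))
print("\ncondensed vs aggregated-resolved at 2000 s:")
print(f"  a: {condensed.a[-1]:.5f} vs {agg.a:.5f} mol/L")
print(f"  c: {condensed.c[-1]:.5f} vs {agg.c:.5f} mol/L")
print(f"\nAt equilibrium c/a = {agg.c / agg.a:.2f} = sqrt(keq) = {params.keq**0.5:.2f}:")
print("the mean degree of polymerization the mixture jumps to before any")
print("water removal; the dispersity approaches the most-probable value ~2.")
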