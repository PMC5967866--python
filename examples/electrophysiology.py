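"""Nernst diffusion potentials and single-channel conductance.

Computes the K+ diffusion potential imposed by valinomycin for a 1:100
in/out KCl gradient, then simulates gated planar-bilayer sweeps of a 92-pS
channel and recovers the unitary conductance from the I-V slope.
"""

from vesiflux import (
    PotentialCondition,
    SimConfig,
    conductance_from_iv,
    nernst_potential,
    simulate_iv,
)

for ratio in (10.0, 100.0):
    e = nernst_potential(PotentialCondition(k_in=1.0, k_out=ratio))
    print(f"K_in:K_out = 1:{ratio:<5.0f} ->  E = {e:+.1f} mV")

iv = simulate_iv(g=92.0, cfg=SimConfig(seed=33), open_prob=0.7, n_channels=1)
fit = conductance_from_iv(iv)
print(f"fitted conductance  {fit.conductance:.1f} +/- {fit.conductance_se:.1f} pS")
print(f"reversal potential  {fit.reversal_potential:+.2f} mV (r^2 = {fit.r_squared:.4f})")

# +59 mV per decade of gradient at 25 C for a monovalent cation; an ohmic
# unitary I-V slope of ~0.092 pA/mV corresponds to 92 pS, with a reversal
# near 0 mV in symmetrical solutions.
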