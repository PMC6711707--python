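"""Cross-check the closed-form adhesion model against exact bond simulation.

The immigration-death process (bonds form at constant rate lam = mr*ml*Ackon,
each dissociates at rate mu = koff) has a Poisson bond count whose
zero-class gives Pa = 1 - exp(-<n>).  Simulated adhesion fractions should
match the closed form to binomial sampling error.
"""

import math

import numpy as np

from fcgrkit.kinetics import DensityPair, KineticParams, adhesion_probability
from fcgrkit.synthetic import BondProcessParams, simulate_bond_count

densities = DensityPair(1500.0, 1500.0)
params = KineticParams(ac_ka=3.03e-7, koff=7.75)
bp = BondProcessParams.from_kinetics(params, densities)
rng = np.random.default_rng(11)

n_draws = 4000
print(f"lam = {bp.lam:.3f} s^-1, mu = {bp.mu:.2f} s^-1, {n_draws} cycles per tc\n")
print(" tc (s)   Pa closed-form   Pa simulated   |diff|/SE")
for tc in (0.1, 0.2, 0.5, 1.0, 2.0):
    p = adhesion_probability(tc, densities, params)
    frac = np.mean([simulate_bond_count(bp, tc, rng=rng) >= 1 for _ in range(n_draws)])
    se = math.sqrt(p * (1 - p) / n_draws)
    print(f"  {tc:4.1f}      {p:.4f}          {frac:.4f}        {abs(frac-p)/se:.2f}")
print("\nDeviations of a few SEs at most confirm the closed form is the "
      "exact zero-bond probability of the stochastic process.")
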