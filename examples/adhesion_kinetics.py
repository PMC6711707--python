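"""Fit 2D adhesion-frequency curves for two receptor variants and compare.

Simulates the standard micropipette experiment (6 contact times, 4 cell
pairs x 50 cycles each) for the 232I and 232T variants binding an IgG1
ligand at their reported kinetic parameters, fits each curve, attaches
bootstrap errors, and reports the fold differences.
"""

import numpy as np

from fcgrkit.datasets import KINETIC_PARAMS
from fcgrkit.kinetics import DensityPair, compare_fits, fit_curve_with_errors
from fcgrkit.synthetic import simulate_adhesion_cycles

densities = DensityPair(mr=1500.0, ml=1500.0)  # molecules per um^2

fits = {}
for variant in ("232I", "232T"):
    truth = KINETIC_PARAMS[f"{variant}_anti-S_IgG1"]
    curve = simulate_adhesion_cycles(truth, densities, seed=1, label=variant)
    fit = fit_curve_with_errors(curve, n_boot=200, seed=1)
    fits[variant] = fit
    p = fit.params
    print(f"{variant}:  AcKa = {p.ac_ka:.3e} +/- {fit.se_ac_ka:.1e} um^4"
          f"   koff = {p.koff:.2f} +/- {fit.se_koff:.2f} s^-1"
          f"   Ackon = {p.ac_kon:.3e} um^4 s^-1")

cmp = compare_fits(fits["232I"], fits["232T"])
print(f"\nAcKa fold (232I/232T) = {cmp.fold_ac_ka:.2f}  (p = {cmp.p_ac_ka:.2g})")
print(f"Ackon fold (232I/232T) = {cmp.fold_ac_kon:.2f}  (p = {cmp.p_ac_kon:.2g})")
print("\nA fold near 3-4 with similar off-rates means the variant mainly "
      "loses binding through a slower effective on-rate, not faster release.")
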