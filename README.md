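# fcgrkit

Quantitative analyses around a disease-associated transmembrane
polymorphism of the inhibitory IgG receptor FcγRIIB (the I232T variant
linked to systemic lupus erythematosus). The variant tilts the receptor's
transmembrane helix, bends the ectodomain toward the membrane, and
weakens in-situ IgG binding; `fcgrkit` implements the four quantitative
pipelines needed to study that chain of effects, each runnable on
synthetic data or on published count tables:

* **kinetics** — the micropipette adhesion-frequency assay's
  probabilistic model of two-dimensional (membrane-anchored)
  receptor–ligand binding. The adhesion probability at contact time
  *t*<sub>c</sub> is

  *P*<sub>a</sub>(*t*<sub>c</sub>) = 1 − exp{ −*m*<sub>r</sub>*m*<sub>l</sub>·*A*<sub>c</sub>*K*<sub>a</sub>·(1 − e<sup>−*k*<sub>off</sub>·*t*<sub>c</sub></sup>) }

  with surface densities *m*<sub>r</sub>, *m*<sub>l</sub> (μm⁻²),
  effective 2D affinity *A*<sub>c</sub>*K*<sub>a</sub> (μm⁴) and
  off-rate *k*<sub>off</sub> (s⁻¹); the effective on-rate is
  *A*<sub>c</sub>*k*<sub>on</sub> = *A*<sub>c</sub>*K*<sub>a</sub>·*k*<sub>off</sub>.
  The module fits (*A*<sub>c</sub>*K*<sub>a</sub>, *k*<sub>off</sub>) by
  binomially weighted nonlinear least squares (or maximum likelihood),
  bootstraps standard errors over cell pairs, applies the assay's
  10⁻⁸ μm⁴ detection limit, and compares conditions as fold changes.
* **fret** — de-quenching (acceptor photobleaching) FRET efficiency
  per cell, *E* = (DQ − Q)/DQ, with group summaries and Welch /
  Mann–Whitney comparisons.
* **genetics** — recessive-model (CC vs TT+TC) case–control statistics:
  a parser for compact published genotype rows
  (`"376+286 (96.2)/26 (3.8)"`), crude odds ratios with Woolf 95%
  confidence intervals, and Pearson chi-square tests.
* **trajgeom** — per-frame geometry descriptors of a membrane-protein
  trajectory (multi-model PDB or CSV): TM helix tilt, ectodomain
  inclination, domain-to-bilayer distance, stalk segment span along the
  membrane normal, backbone φ/ψ, atom-pair distances with an H-bond
  call, and probability-distribution summaries.
* **synthetic** — seeded generators for all of the above, including an
  exact immigration–death (Gillespie) bond simulator that serves as the
  stochastic oracle for the closed-form kinetic model, and a toy
  membrane-receptor trajectory builder with known ground-truth geometry.

The package is a library: import it from Python, or run the short
narrative scripts in `examples/` (one per capability).

## Worked example

Simulate the standard adhesion-frequency experiment (contact times
0.1–5 s, 4 cell pairs × 50 cycles each) for the two receptor variants at
their reported kinetic parameters, then fit and compare
(`python examples/adhesion_kinetics.py`):

```
232I:  AcKa = 2.958e-07 +/- 6.4e-09 um^4   koff = 8.60 +/- 0.75 s^-1   Ackon = 2.545e-06 um^4 s^-1
232T:  AcKa = 6.849e-08 +/- 6.0e-09 um^4   koff = 8.23 +/- 2.17 s^-1   Ackon = 5.639e-07 um^4 s^-1

AcKa fold (232I/232T) = 4.32  (p = 2.7e-58)
Ackon fold (232I/232T) = 4.51  (p = 1.7e-09)
```

The fitted affinities recover the generating values (3.03×10⁻⁷ and
0.80×10⁻⁷ μm⁴) to within the experiment's sampling error: the wild-type
receptor binds IgG1 several-fold more strongly, the off-rates are
statistically indistinguishable, so the difference is carried by the
effective on-rate — the binding-site presentation, not bond stability.

Similarly, `python examples/genetics_table.py` prints the whole-cohort
recessive association

```
whole cohort: crude OR = 1.926 (95% CI 1.18-3.13), chi2 = 7.20, p = 0.0073
```

and `python examples/fret_comparison.py` the two-fold FRET enhancement
on synthetic cells (20.1% vs 41.4% mean efficiency, p < 10⁻¹¹).

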