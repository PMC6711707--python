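# Methods

This note documents the models, estimators, numerical choices and known
limitations of `fcgrkit`, in the order of the analysis pipelines.

## 2D adhesion-frequency kinetics

**Model.** With a receptor-bearing cell and a ligand-coated cell in
repeated contact–retraction cycles, bonds form between membrane-anchored
partners inside a contact area *A*c. Treating bond formation as an
immigration–death process — formation at constant rate
λ = *m*r·*m*l·*A*c*k*on, dissociation of each bond at rate μ = *k*off —
the bond count at contact time *t*c is Poisson with mean
⟨n⟩ = *m*r·*m*l·*A*c*K*a·(1 − e^(−*k*off·*t*c)), and the adhesion
probability (≥1 bond) is *P*a = 1 − e^(−⟨n⟩). The contact area and
intrinsic affinity are never separable in this assay, so only the
products *A*c*K*a (μm⁴) and *A*c*k*on = *A*c*K*a·*k*off (μm⁴ s⁻¹) are
reported — the package enforces that identity exactly rather than
treating the on-rate as an independent parameter. Units are fixed
(densities μm⁻², affinity μm⁴, rates s⁻¹); no unit inference is done.

**Fitting.** Cycles are pooled per contact time. The default objective
is weighted least squares on pooled frequencies with binomial variance
weights p̂(1−p̂)/n; to keep all-zero or all-one contact times at finite
weight, p̂(1−p̂) is floored at 1/(4n). A binomial maximum-likelihood
objective is available (`method="mle"`) and agrees with WLS within the
reported standard errors on clean data. Optimization runs in
(log *A*c*K*a, log *k*off) space, which enforces positivity, with a
deterministic multi-start grid: *A*c*K*a seeded by inverting the
observed plateau, *k*off ∈ {0.1, 1, 10} s⁻¹, bounds 10⁻¹³–10⁻² μm⁴ and
10⁻³–10³ s⁻¹. No background-adhesion term is subtracted by default; the
assay protocol reports none.

**Uncertainty.** The replication unit is the cell pair (3–4 pairs per
contact time), so standard errors come from a bootstrap that resamples
pairs with replacement within each contact time and refits
(default 1000 resamples; fully seeded). When the curve is weakly
informative about *k*off the bootstrap distribution is heavy-tailed and
the SE honest-but-large; comparisons on the log scale (delta-method z
tests in `compare_fits`) are the intended use.

**Detection limit.** An all-zero curve, or a fitted affinity below
10⁻⁸ μm⁴ (configurable), is reported as not-detectable (ND) and blocked
from numeric comparison. This mirrors how conditions like IgG4 binding
are reported in this assay.

**Identifiability at experiment scale.** With the default schedule the
shortest contact time (0.1 s) is comparable to 1/*k*off ≈ 0.12 s, so
*k*off is informed mainly by two points and its estimator is noticeably
more variable than the affinity's (replicate-mean recovery bands in the
tests: 10% for *A*c*K*a, 20% for *k*off over 25 replicates).
This is a property of the assay design, not of the optimizer.

## Synthetic data

All generators are pure functions of their inputs and an integer seed.

* **Adhesion cycles.** Defaults follow the standard protocol: contact
  times (0.1, 0.2, 0.5, 1, 2, 5) s — the published schedule says "2 s or
  longer", and 5 s is adopted as the longest point — 4 cell pairs per
  contact time, 50 cycles per pair, densities supplied by the caller
  (1500 μm⁻² in the examples). `closed_form` mode draws cycles as
  Bernoulli trials at the model probability; `gillespie` mode simulates
  the immigration–death process exactly and scores a cycle adhesive when
  ≥1 bond exists at *t*c. The two agree to binomial sampling error, which
  is the package's dual-route check of the closed form. Per-cycle contact
  mechanics (impingement force, retraction speed) are abstracted away: a
  cycle is "bond present at *t*c or not", which is all the model uses.
* **FRET cells.** De-quenched intensity is a base level (default 1000
  a.u.) under multiplicative lognormal noise with a given CV (default
  10% — typical for gain-dominated fluorescence readouts); the quenched
  intensity is DQ·(1−E) under an independent factor of the same CV.
  Noise factors have unit mean, so the group mean efficiency is an
  unbiased estimate of the generating efficiency. No pixel-level image
  synthesis is attempted.
* **Genotype cohorts.** Controls are binomial in the CC genotype at a
  given frequency; the case probability follows from multiplying the
  control odds by the recessive odds ratio,
  p = qOR/(1 + q(OR − 1)). Covariates (age, sex) are not modelled,
  so simulated cohorts can only validate *crude* estimators.
* **Toy trajectories.** Built in the laboratory frame with the bilayer
  normal along +z: a 3×3 phosphate-marker grid at z = 0, a straight TM
  pseudo-helix of Cα atoms (residues 222–248, the published numbering,
  so descriptor selections work unchanged) at the requested tilt, linker
  markers placed to realize the requested ectodomain inclination,
  an equal-mass domain cluster at the requested height, and full
  backbones for the two stalk residues at the requested normal span.
  Atom positions around each construction point are symmetric, so
  jitter-free descriptors equal the specification to numerical
  precision; per-atom Gaussian jitter adds realistic frame-to-frame
  scatter. The builder makes no attempt at force-field realism — it is
  ground truth for the descriptor suite, not a physical model.

Because the generators draw from the same model families the estimators
assume, passing recovery tests demonstrates correctness of the
estimators, not robustness to real-data pathologies (nonspecific
adhesion, bleed-through, population stratification, membrane
undulations).

## FRET efficiency

E = (DQ − Q)/DQ per cell, after subtracting an optional shared
background from both intensities. Cells with Q ≥ DQ (photobleach
failure) get E ≤ 0 and are *flagged, not dropped*; exclusion is an
explicit argument. Group summaries report mean, SEM and median (published
group efficiencies are sometimes medians; reporting both sidesteps the
ambiguity). The default two-group test is Welch's t on per-cell
efficiencies — standard practice at ~20 cells per group — with a
Mann–Whitney option, and an automatic fallback to the rank test when a
group of fewer than three cells has zero variance. Förster-distance
modelling and crosstalk correction are out of scope.

## Recessive-model genetics

The 2×2 table is CC vs TT+TC by cases/controls. The crude odds ratio
uses the cross-product with a Woolf (log-scale) 95% CI,
exp(ln OR ± 1.96·√(Σ1/cell)); when any cell is zero the
Haldane–Anscombe +0.5 is added to all cells and the result flagged
(several small strata need it). The Pearson chi-square uses no
continuity correction by default (Yates behind a flag); its p-value is
the χ²(1) survival function. Display percentages round half-up to one
decimal, matching the published table convention, with full precision
retained internally.

Published per-stratum odds ratios from this study design are logistic
regression estimates adjusted for age and sex; without individual-level
covariates those are not reproducible, and the package deliberately
reports crude ORs (e.g. crude 2.00 vs adjusted 2.739 for the early-onset
stratum). The whole-cohort headline triple (χ² = 27.224, p = 0.008,
OR = 1.927) is internally inconsistent for a 1-df test — the crude 2×2
gives χ² ≈ 7.20, p ≈ 0.0073, OR ≈ 1.926 — so the package reports the
crude statistics and leaves the published χ² unmatched rather than
guessing the original test's degrees of freedom.

## Trajectory geometry

The membrane plane is a least-squares (SVD) plane through user-selected
anchor atoms, refit per frame; a fixed z-plane mode exists for toy data.
The normal is oriented toward +z by default (the laboratory convention
when the bilayer lies flat) or toward a user-supplied reference group —
required for signed descriptors to be invariant under rigid
transformation of an arbitrarily oriented structure.

* **Helix tilt**: first principal axis (SVD) of the selected Cα
  coordinates, oriented N→C, folded into [0°, 90°] against the plane.
  The principal axis is exact on straight helices and the standard
  estimator elsewhere.
* **Ectodomain inclination**: signed angle in [−90°, 90°] of the vector
  between two residue-group centroids (defaults: TM N-terminal 222–224 →
  linker 130–132), Cα-only by default with all-atom selections possible.
  Negative means pointing into the bilayer; magnitudes are what
  published angle histograms show.
* **Domain–membrane distance**: signed normal projection of the domain
  centre of mass relative to the anchor centroid; masses from standard
  atomic weights inferred from atom names, unit-mass fallback with a
  warning.
* **Segment normal span**: absolute normal-projection difference of two
  residues' N/Cα/C/O centroids.
* **Dihedrals**: standard IUPAC φ/ψ via the praxeolitic formulation,
  signed in (−180°, 180°]; cross-checked against MDAnalysis in the
  tests.
* **Distributions**: histograms with edges aligned to multiples of the
  bin width (defaults 2° for angles, 0.5 Å for distances), probabilities
  normalized to 1, mode reported as the centre of the most probable bin.

Trajectory dialects are multi-model PDB (via biotite; note the format's
10⁻³ Å precision) and a plain per-frame CSV that round-trips exactly.
No MD engine integration, trajectory alignment, or lipid analysis is
included, and the original simulation trajectories behind the published
distributions are not deposited — the toy-trajectory round-trip and
property tests stand in for them.

## Problem sizes

Test-suite and acceptance runs use the study-scale defaults throughout:
25 replicate experiments per kinetic condition, 2 000 cycles per
Gillespie comparison point, 10 000 draws for the Poisson marginal check,
1 000 simulated cohorts for CI coverage, 200 jittered frames for
descriptor scatter. These sizes put Monte-Carlo error well inside each
assertion band while keeping a full run at a few tens of seconds.
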