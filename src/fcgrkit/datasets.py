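"""Published study inputs used by examples, tests and the acceptance script.

These constants transcribe the printed inputs of the FcγRIIB-I232T
association study: the subphenotype genotype table (compact row dialect),
the cohort sizes, the fitted 2D kinetic parameter sets per
receptor-variant/ligand condition, and the reported FRET efficiencies.
"""

from __future__ import annotations

from .kinetics import KineticParams

#: Controls row of the genotype table ("TT+TC (pct)/CC (pct)").
CONTROL_ROW = "376+286 (96.2)/26 (3.8)"

#: Subphenotype rows of the genotype table, in printed order.
TABLE1_ROWS: list[tuple[str, str]] = [
    ("Disease Onset, age < 37", "207+150 (92.7)/28 (7.3)"),
    ("Disease Onset, age >= 37", "171+133 (93.3)/22 (6.7)"),
    ("Arthritis = 1", "203+166 (92.5)/30 (7.5)"),
    ("Arthritis = 0", "132+87 (94.8)/12 (5.2)"),
    ("Hematological involvement = 1", "242+185 (93.4)/30 (6.6)"),
    ("Hematological involvement = 0", "90+75 (94.8)/9 (5.2)"),
    ("Anemia = 1", "126+94 (91.7)/20 (8.3)"),
    ("Anemia = 0", "153+125 (94.2)/17 (5.8)"),
    ("Leukopenia = 1", "140+114 (91.7)/23 (8.3)"),
    ("Leukopenia = 0", "136+107 (94.9)/13 (5.1)"),
    ("dsDNA = 1", "198+151 (92.1)/30 (7.9)"),
    ("dsDNA = 0", "129+94 (94.5)/13 (5.5)"),
    ("ANA = 1", "308+241 (93.4)/39 (6.6)"),
    ("ANA = 0", "25+16 (93.2)/3 (6.8)"),
    ("Total Ig = 1", "131+101 (92.8)/18 (7.2)"),
    ("Total Ig = 0", "120+88 (93.7)/14 (6.3)"),
    ("Complement Decrease = 1", "227+162 (92.4)/32 (7.6)"),
    ("Complement Decrease = 0", "58+54 (95.7)/5 (4.3)"),
    ("Hematuria = 1", "95+65 (90.9)/16 (9.1)"),
    ("Hematuria = 0", "180+140 (94.7)/18 (5.3)"),
    ("Leucocyturia = 1", "64+57 (91.0)/12 (9.0)"),
    ("Leucocyturia = 0", "196+143 (93.9)/22 (6.1)"),
    ("Serositis = 1", "66+45 (92.5)/9 (7.5)"),
    ("Serositis = 0", "225+174 (94.1)/25 (5.9)"),
    ("SLEDAI >= 12", "20+25 (88.2)/6 (11.8)"),
    ("SLEDAI < 12", "116+93 (95.9)/9 (4.1)"),
]

#: Whole-cohort recessive counts: 711 cases (50 CC), 688 controls (26 CC).
COHORT_CASES_CC = 50
COHORT_CASES_OTHER = 661
COHORT_CONTROLS_CC = 26
COHORT_CONTROLS_OTHER = 662

#: Reported adjusted recessive odds ratio for the whole cohort.
REPORTED_COHORT_OR = 1.927

#: Fitted 2D kinetic parameters per condition (AcKa in μm⁴, koff in s⁻¹).
KINETIC_PARAMS: dict[str, KineticParams] = {
    "232I_anti-S_IgG1": KineticParams(ac_ka=3.03e-7, koff=7.75),
    "232T_anti-S_IgG1": KineticParams(ac_ka=0.80e-7, koff=7.62),
    "232I_anti-gp120_IgG1": KineticParams(ac_ka=7.74e-7, koff=7.70),
    "232T_anti-gp120_IgG1": KineticParams(ac_ka=2.43e-7, koff=8.90),
}

#: Reported de-quenching FRET efficiencies (fraction) per variant.
FRET_EFFICIENCY = {"232I": 0.20, "232T": 0.40}
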