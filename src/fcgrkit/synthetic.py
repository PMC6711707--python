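"""Seeded generators for every input the analysis modules consume.

Four families of synthetic data:

* adhesion-frequency experiments — per-cycle Bernoulli outcomes drawn
  either from the closed-form adhesion probability or from an exact
  immigration–death (Gillespie) bond simulation, following the standard
  experiment schedule (contact times 0.1–5 s, 4 cell pairs × 50 cycles);
* per-cell FRET intensity pairs with a known quenching fraction and
  multiplicative lognormal intensity noise;
* case–control genotype cohorts under a recessive odds model;
* toy membrane-protein trajectories whose tilt, inclination, domain
  distance and stalk span are known by construction.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .fret import FretCellMeasurement
from .genetics import RecessiveTable
from .kinetics import (
    AdhesionCurve,
    DensityPair,
    KineticParams,
    adhesion_probability,
    curve_from_cycles,
)
from .trajgeom import Frame

__all__ = [
    "ExperimentSchedule",
    "BondProcessParams",
    "SyntheticTrajectorySpec",
    "simulate_cycle_table",
    "simulate_adhesion_cycles",
    "simulate_bond_count",
    "simulate_fret_cells",
    "simulate_genotype_cohort",
    "build_toy_trajectory",
]


@dataclass(frozen=True)
class ExperimentSchedule:
    """Contact-time schedule of an adhesion-frequency experiment.

    Defaults mirror the standard protocol: contact times 0.1, 0.2, 0.5,
    1, 2 and 5 s, 4 cell pairs per contact time, 50 contact–retraction
    cycles per pair.
    """

    tc_list: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
    pairs_per_tc: int = 4
    cycles_per_pair: int = 50

    def __post_init__(self) -> None:
        if any(tc <= 0 for tc in self.tc_list):
            raise ValueError("all contact times must be positive")
        if self.pairs_per_tc < 1 or self.cycles_per_pair < 1:
            raise ValueError("pairs_per_tc and cycles_per_pair must be >= 1")


@dataclass(frozen=True)
class BondProcessParams:
    """Immigration–death bond process rates.

    ``lam`` is the bond formation rate mr·ml·Ackon (s⁻¹, independent of
    the current bond count) and ``mu`` the per-bond dissociation rate
    koff (s⁻¹); the stationary mean lam/mu equals mr·ml·AcKa.
    """

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("formation rate must be non-negative")
        if self.mu <= 0:
            raise ValueError("dissociation rate must be positive")

    @staticmethod
    def from_kinetics(params: KineticParams, densities: DensityPair) -> "BondProcessParams":
        return BondProcessParams(
            lam=densities.product * params.ac_kon, mu=params.koff
        )

    def mean_bonds(self, t: float) -> float:
        """Poisson mean (lam/mu)(1 − exp(−mu t)) of the bond count at t."""
        return (self.lam / self.mu) * -math.expm1(-self.mu * t)


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Ground-truth geometry for a toy membrane-receptor trajectory.

    Angles in degrees (must lie in (0°, 90°]), distances in Å.  With
    ``jitter_sd=0`` the descriptor suite recovers every field exactly.
    """

    tilt_deg: float = 40.0
    incl_deg: float = 40.0
    d_c1: float = 30.0
    span_s218_p221: float = 11.0
    n_frames: int = 1
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for ang in (self.tilt_deg, self.incl_deg):
            if not 0.0 < ang <= 90.0:
                raise ValueError("angles must lie in (0, 90] degrees")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


# ---------------------------------------------------------------------------
# Adhesion cycles
# ---------------------------------------------------------------------------

def _bond_count(rng: np.random.Generator, lam: float, mu: float, t: float) -> int:
    """One exact immigration–death trajectory, returning the count at t."""
    n = 0
    now = 0.0
    while True:
        total = lam + n * mu
        if total <= 0.0:
            return n
        now += rng.exponential(1.0 / total)
        if now > t:
            return n
        if rng.random() < lam / total:
            n += 1
        else:
            n -= 1


def simulate_bond_count(
    params: BondProcessParams, t: float, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Exact bond count of the immigration–death process at time ``t``.

    Bonds form at constant rate ``lam`` and each dissociates at rate
    ``mu``; starting from zero bonds the marginal count at ``t`` is
    Poisson with mean (lam/mu)(1 − exp(−mu t)) — this simulator is the
    stochastic oracle for the closed-form adhesion model.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _bond_count(rng, params.lam, params.mu, t)


def simulate_cycle_table(
    params: KineticParams,
    densities: DensityPair,
    schedule: ExperimentSchedule = ExperimentSchedule(),
    mode: Literal["closed_form", "gillespie"] = "closed_form",
    seed: int = 0,
) -> pd.DataFrame:
    """Cycle-level table of a simulated adhesion-frequency experiment.

    ``closed_form`` draws each cycle as an independent Bernoulli success
    with probability Pa(tc); ``gillespie`` scores a cycle as adhesive
    when the exact bond process holds ≥1 bond at tc.  Output columns are
    ``cell_pair_id, tc_s, cycle_index, adhesion`` — the same dialect the
    fitter reads — and are bitwise reproducible per seed.
    """
    if mode not in ("closed_form", "gillespie"):
        raise ValueError(f"unknown simulation mode: {mode!r}")
    rng = np.random.default_rng(seed)
    bond = BondProcessParams.from_kinetics(params, densities)
    rows: list[tuple[str, float, int, int]] = []
    for tc in schedule.tc_list:
        pa = adhesion_probability(tc, densities, params)
        for pair in range(schedule.pairs_per_tc):
            pair_id = f"tc{tc:g}_pair{pair}"
            if mode == "closed_form":
                outcomes = (rng.random(schedule.cycles_per_pair) < pa).astype(int)
            else:
                outcomes = np.array(
                    [
                        int(_bond_count(rng, bond.lam, bond.mu, tc) >= 1)
                        for _ in range(schedule.cycles_per_pair)
                    ]
                )
            rows.extend(
                (pair_id, tc, cyc, int(adh))
                for cyc, adh in enumerate(outcomes)
            )
    return pd.DataFrame(rows, columns=["cell_pair_id", "tc_s", "cycle_index", "adhesion"])


def simulate_adhesion_cycles(
    params: KineticParams,
    densities: DensityPair,
    schedule: ExperimentSchedule = ExperimentSchedule(),
    mode: Literal["closed_form", "gillespie"] = "closed_form",
    seed: int = 0,
    label: str = "",
) -> AdhesionCurve:
    """Simulate an adhesion-frequency experiment as an :class:`AdhesionCurve`."""
    table = simulate_cycle_table(params, densities, schedule, mode, seed)
    return curve_from_cycles(table, densities, label=label)


# ---------------------------------------------------------------------------
# FRET cells
# ---------------------------------------------------------------------------

def simulate_fret_cells(
    true_e: float,
    base_intensity: float = 1000.0,
    n_cells: int = 20,
    noise_cv: float = 0.10,
    seed: int = 0,
    group: str = "",
) -> list[FretCellMeasurement]:
    """Per-cell quenched/de-quenched donor intensities at known efficiency.

    The de-quenched intensity is ``base_intensity`` under multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` (intensity
    readouts are positive and gain-dominated); the quenched intensity is
    DQ·(1 − true_e) under an independent noise factor of the same CV.
    The noise factors have unit mean, so the group mean efficiency
    converges to ``true_e`` as the cell count grows.
    """
    if not 0.0 <= true_e < 1.0:
        raise ValueError("true efficiency must lie in [0, 1)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    if noise_cv == 0.0:
        factors = np.ones((n_cells, 2))
    else:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(n_cells, 2)))
    cells = []
    for i in range(n_cells):
        dq = base_intensity * factors[i, 0]
        q = dq * (1.0 - true_e) * factors[i, 1]
        cells.append(
            FretCellMeasurement(cell_id=f"cell{i:03d}", q=q, dq=dq, group=group)
        )
    return cells


# ---------------------------------------------------------------------------
# Genotype cohorts
# ---------------------------------------------------------------------------

def simulate_genotype_cohort(
    control_cc_freq: float,
    or_recessive: float,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    label: str = "",
) -> RecessiveTable:
    """Case–control cohort under a recessive odds model.

    Controls carry the CC genotype with probability ``control_cc_freq``;
    the case CC probability follows from multiplying the control odds by
    ``or_recessive``: p_case = q·OR / (1 + q·(OR − 1)) with q the
    control frequency.  Counts are binomial draws; ``n_cases=0`` yields
    a valid table with an empty case margin.
    """
    if not 0.0 < control_cc_freq < 1.0:
        raise ValueError("control CC frequency must lie in (0, 1)")
    if or_recessive <= 0:
        raise ValueError("odds ratio must be positive")
    if n_cases < 0 or n_controls < 0:
        raise ValueError("cohort sizes must be non-negative")
    q = control_cc_freq
    p_case = q * or_recessive / (1.0 + q * (or_recessive - 1.0))
    rng = np.random.default_rng(seed)
    cases_cc = int(rng.binomial(n_cases, p_case)) if n_cases else 0
    controls_cc = int(rng.binomial(n_controls, q)) if n_controls else 0
    return RecessiveTable(
        cases_cc=cases_cc, cases_other=n_cases - cases_cc,
        controls_cc=controls_cc, controls_other=n_controls - controls_cc,
        label=label,
    )


# ---------------------------------------------------------------------------
# Toy trajectories
# ---------------------------------------------------------------------------

def _zero_sum_offsets() -> np.ndarray:
    # Four offsets summing to zero: backbone atoms spread around their
    # centroid so the centroid is exactly the anchor point.
    return np.array(
        [[0.7, 0.0, 0.0], [-0.7, 0.0, 0.0], [0.0, 0.7, 0.0], [0.0, -0.7, 0.0]]
    )


def build_toy_trajectory(spec: SyntheticTrajectorySpec) -> list[Frame]:
    """Toy membrane-receptor trajectory with known geometry.

    The laboratory frame has the bilayer normal along +z and the
    phosphate-marker plane at z = 0.  Each frame contains:

    * a 3×3 grid of lipid phosphate markers (chain M, atom P) at z ≈ 0;
    * a straight TM pseudo-helix of Cα atoms (residues 222–248,
      chain A) descending into the bilayer at the requested tilt, with a
      side-chain Oγ on residue 232 and a backbone O on residue 228;
    * linker markers (residues 130–132 Cα) placed so the vector from the
      TM N-terminal centroid (222–224) realizes the requested
      ectodomain inclination;
    * a C1-domain cluster (Cα atoms, residues 50–80) whose centre of
      mass sits ``d_c1`` above the plane;
    * full N/Cα/C/O backbones for residues 218 and 221 separated by the
      requested normal span.

    Gaussian jitter of sd ``jitter_sd`` is added per atom per frame; a
    jitter-free build is recovered exactly by the descriptor suite.
    """
    tilt = math.radians(spec.tilt_deg)
    incl = math.radians(spec.incl_deg)

    names: list[str] = []
    res_num: list[int] = []
    res_name: list[str] = []
    chain: list[str] = []
    coords: list[np.ndarray] = []

    def add(name: str, num: int, rname: str, ch: str, xyz) -> None:
        names.append(name)
        res_num.append(num)
        res_name.append(rname)
        chain.append(ch)
        coords.append(np.asarray(xyz, dtype=float))

    # Phosphate-marker plane at z = 0.
    k = 1001
    for gx in (-20.0, 0.0, 20.0):
        for gy in (-20.0, 0.0, 20.0):
            add("P", k, "LIP", "M", (gx, gy, 0.0))
            k += 1

    # Straight TM pseudo-helix: residue 222 at the head-group plane,
    # descending N->C into the bilayer at the requested tilt.
    u = np.array([math.cos(tilt), 0.0, -math.sin(tilt)])
    p0 = np.array([0.0, 0.0, 0.0])
    helix_res = {228: "VAL", 232: "THR"}
    ca_pos = {}
    for i, res in enumerate(range(222, 249)):
        pos = p0 + 1.5 * i * u
        ca_pos[res] = pos
        add("CA", res, helix_res.get(res, "ALA"), "A", pos)
    add("OG1", 232, "THR", "A", ca_pos[232] + np.array([0.0, 1.3, 0.8]))
    add("O", 228, "VAL", "A", ca_pos[228] + np.array([0.0, 1.2, 0.9]))

    # Linker markers realizing the ectodomain inclination from the TM
    # N-terminal centroid (residues 222-224).
    c_tm = (ca_pos[222] + ca_pos[223] + ca_pos[224]) / 3.0
    v = np.array([math.cos(incl), 0.0, math.sin(incl)])
    c_linker = c_tm + 45.0 * v
    for j, res in enumerate((130, 131, 132)):
        offset = np.array([0.0, (j - 1) * 1.0, 0.0])
        add("CA", res, ("SER", "GLY", "TRP")[j], "A", c_linker + offset)

    # C1 domain cluster: all-carbon, centroid (== COM) at z = d_c1.
    c1_center = np.array([10.0, 0.0, spec.d_c1])
    for j, res in enumerate((50, 60, 70, 80)):
        offset = np.array(
            [[4.0, 0.0, 2.0], [-4.0, 0.0, -2.0], [0.0, 4.0, 1.0], [0.0, -4.0, -1.0]]
        )[j]
        add("CA", res, "GLY", "A", c1_center + offset)

    # Stalk residues 218 (upper) and 221 (lower): backbone centroids
    # separated by the requested span along the membrane normal.
    q221 = np.array([-5.0, 0.0, 1.0])
    q218 = q221 + np.array([0.0, 0.0, spec.span_s218_p221])
    for res, rname, center in ((218, "SER", q218), (221, "PRO", q221)):
        for atom, offset in zip(("N", "CA", "C", "O"), _zero_sum_offsets()):
            add(atom, res, rname, "A", center + offset)

    base = np.vstack(coords)
    name_arr = np.array(names, dtype="U6")
    num_arr = np.array(res_num, dtype=int)
    rname_arr = np.array(res_name, dtype="U4")
    chain_arr = np.array(chain, dtype="U2")

    rng = np.random.default_rng(spec.seed)
    frames = []
    for fi in range(spec.n_frames):
        xyz = base.copy()
        if spec.jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sd, size=xyz.shape)
        frames.append(
            Frame(fi, name_arr.copy(), num_arr.copy(), rname_arr.copy(),
                  chain_arr.copy(), xyz)
        )
    return frames
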