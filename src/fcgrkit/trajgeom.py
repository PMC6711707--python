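"""Per-frame geometric descriptors of membrane-protein trajectories.

Descriptors quantify how a single-pass receptor sits in and above the
bilayer: the tilt of the transmembrane (TM) helix relative to the
membrane plane, the inclination of the ectodomain above the plane, the
normal-direction distance from a domain's centre of mass to the
phosphate plane, the normal-direction span of a stalk segment, backbone
dihedrals, and atom-pair distances with a hydrogen-bond call.  Each is
computed per frame; distributions are summarized as normalized
probability histograms.

Trajectories are multi-model PDB files (read through biotite) or a plain
per-frame coordinate CSV; in memory a frame is a light struct of
parallel numpy arrays.  Selections use the mini-language
``"chain:resnums:atom"`` with ``*`` wildcards and residue ranges, e.g.
``"A:222-248:CA"`` or ``"*:*:P"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "MembraneModel",
    "DescriptorSeries",
    "Histogram",
    "PairDistance",
    "select",
    "membrane_plane",
    "helix_tilt_angle",
    "ectodomain_inclination",
    "domain_membrane_distance",
    "segment_normal_length",
    "backbone_dihedrals",
    "atom_pair_distance",
    "probability_distribution",
    "compute_series",
    "read_trajectory",
    "write_trajectory",
    "frames_from_csv",
    "frames_to_csv",
]

# Standard atomic masses for centre-of-mass weighting.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Frame:
    """One trajectory snapshot: parallel per-atom annotation arrays."""

    frame_index: int
    atom_name: np.ndarray  # (n,) str
    res_num: np.ndarray    # (n,) int
    res_name: np.ndarray   # (n,) str
    chain: np.ndarray      # (n,) str
    coords: np.ndarray     # (n, 3) float, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        if n == 0:
            raise ValueError("frame must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for arr in (self.atom_name, self.res_num, self.res_name, self.chain):
            if len(arr) != n:
                raise ValueError("annotation arrays must match coords length")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "Frame":
        return Frame(
            self.frame_index, self.atom_name[mask], self.res_num[mask],
            self.res_name[mask], self.chain[mask], self.coords[mask],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Rigidly transform all coordinates (x -> R x + t)."""
        return Frame(
            self.frame_index, self.atom_name, self.res_num,
            self.res_name, self.chain,
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )


def _parse_resnum_term(term: str, res_num: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(res_num), dtype=bool)
    for part in term.split(","):
        part = part.strip()
        if part == "*":
            mask[:] = True
        elif "-" in part[1:]:  # allow a leading minus only for literals
            lo, hi = part.split("-", 1)
            mask |= (res_num >= int(lo)) & (res_num <= int(hi))
        else:
            mask |= res_num == int(part)
    return mask


def select(frame: Frame, spec: str) -> Frame:
    """Select atoms with ``"chain:resnums:atom"`` (``*`` wildcards).

    ``resnums`` accepts single numbers, ranges ("222-248") and
    comma-lists; the atom field may be omitted.  Examples:
    ``"A:222-248:CA"``, ``"*:130-132"``, ``"*:*:P"``.
    """
    parts = spec.split(":")
    if len(parts) == 2:
        parts.append("*")
    if len(parts) != 3:
        raise ValueError(f"bad selection {spec!r}; expected chain:resnums[:atom]")
    chain_term, res_term, atom_term = (p.strip() for p in parts)
    mask = np.ones(frame.n_atoms, dtype=bool)
    if chain_term != "*":
        mask &= np.isin(frame.chain, [c.strip() for c in chain_term.split(",")])
    if res_term != "*":
        mask &= _parse_resnum_term(res_term, frame.res_num)
    if atom_term != "*":
        mask &= np.isin(frame.atom_name, [a.strip() for a in atom_term.split(",")])
    return frame.subset(mask)


# ---------------------------------------------------------------------------
# Membrane plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneModel:
    """A plane x·normal = offset; ``normal`` is unit and points toward +z."""

    normal: np.ndarray
    offset: float
    source: str = "fitted"  # "fitted" | "fixed"

    @staticmethod
    def fixed_z(z: float = 0.0) -> "MembraneModel":
        """Laboratory-frame plane z = const (toy/synthetic data)."""
        return MembraneModel(np.array([0.0, 0.0, 1.0]), float(z), source="fixed")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


def membrane_plane(
    frame: Frame, anchor_selection: str, orient_toward: str | None = None
) -> MembraneModel:
    """Least-squares plane through anchor atoms (e.g. lipid phosphates).

    Needs ≥3 non-collinear anchors.  By default the normal is oriented
    toward positive z (the laboratory convention when the bilayer lies
    flat); for arbitrarily oriented structures pass ``orient_toward``, a
    selection (e.g. an ectodomain group) whose centroid defines the
    positive side — signed descriptors are then invariant under rigid
    transformation of the whole frame.
    """
    anchors = select(frame, anchor_selection)
    pts = anchors.coords
    if len(pts) < 3:
        raise ValueError("membrane plane needs at least 3 anchor atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # Smallest principal direction of the anchor cloud is the normal.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("anchor atoms are collinear; plane undefined")
    normal = vt[2]
    if orient_toward is not None:
        ref = select(frame, orient_toward)
        if ref.n_atoms == 0:
            raise ValueError(f"orientation selection {orient_toward!r} is empty")
        if normal @ (ref.coords.mean(axis=0) - centroid) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    return MembraneModel(normal, float(centroid @ normal), source="fitted")


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate selection: zero spatial variance")
    return vt[0]


def helix_tilt_angle(
    frame: Frame, helix_ca_selection: str, plane: MembraneModel
) -> float:
    """Tilt of a TM helix relative to the membrane plane, degrees.

    The helix axis is the first principal axis (SVD) of the selected Cα
    coordinates, oriented N→C by residue number; the tilt is the angle
    between that axis and the plane, folded into [0°, 90°] (90° = helix
    perpendicular to the membrane).
    """
    ca = select(frame, helix_ca_selection)
    if ca.n_atoms < 4:
        raise ValueError("helix axis needs at least 4 Cα atoms")
    order = np.argsort(ca.res_num, kind="stable")
    pts = ca.coords[order]
    axis = _principal_axis(pts)
    if axis @ (pts[-1] - pts[0]) < 0:
        axis = -axis
    sin_t = np.clip(abs(axis @ plane.normal), 0.0, 1.0)
    return math.degrees(math.asin(sin_t))


def ectodomain_inclination(
    frame: Frame,
    plane: MembraneModel,
    tm_selection: str = "*:222-224:CA",
    linker_selection: str = "*:130-132:CA",
) -> float:
    """Ectodomain inclination above the membrane plane, degrees.

    Angle of the vector from the TM N-terminal centroid (default
    residues 222-224) to the inter-domain linker centroid (default
    130-132) above the plane, signed in [−90°, 90°]; negative values
    point into the bilayer.  Cα-only centroids by default — pass
    selections without the ``:CA`` suffix for all-atom centroids.
    """
    tm = select(frame, tm_selection)
    linker = select(frame, linker_selection)
    if tm.n_atoms == 0 or linker.n_atoms == 0:
        raise ValueError("missing residue group for inclination vector")
    v = linker.coords.mean(axis=0) - tm.coords.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate inclination vector")
    sin_i = np.clip((v @ plane.normal) / norm, -1.0, 1.0)
    return math.degrees(math.asin(sin_i))


def _element_of(atom_name: str) -> str:
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    return stripped[:1].upper() if stripped else ""


def domain_membrane_distance(
    frame: Frame, domain_selection: str, plane: MembraneModel
) -> float:
    """Signed normal distance from a domain's COM to the membrane plane (Å).

    The centre of mass uses standard atomic masses inferred from atom
    names; unknown elements fall back to unit mass with a warning.
    Positive values lie on the +normal (extracellular) side.
    """
    domain = select(frame, domain_selection)
    if domain.n_atoms == 0:
        raise ValueError("empty domain selection")
    masses = np.empty(domain.n_atoms)
    unknown = False
    for i, name in enumerate(domain.atom_name):
        m = _MASSES.get(_element_of(str(name)))
        if m is None:
            unknown = True
            m = 1.0
        masses[i] = m
    if unknown:
        warnings.warn("unknown element(s); unit masses used for COM", RuntimeWarning)
    com = masses @ domain.coords / masses.sum()
    return float(com @ plane.normal - plane.offset)


def segment_normal_length(
    frame: Frame, res_a: int, res_b: int, plane: MembraneModel, chain: str = "*"
) -> float:
    """Normal-direction span between two residues' backbone centroids (Å).

    Uses the N/Cα/C/O backbone centroid of each residue projected onto
    the membrane normal; returns the absolute difference.
    """
    centroids = []
    for res in (res_a, res_b):
        atoms = select(frame, f"{chain}:{res}:{','.join(BACKBONE_ATOMS)}")
        if atoms.n_atoms < len(BACKBONE_ATOMS):
            raise ValueError(f"residue {res}: incomplete backbone (need N, CA, C, O)")
        centroids.append(atoms.coords.mean(axis=0))
    return float(abs((centroids[0] - centroids[1]) @ plane.normal))


def _dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    # Signed dihedral (praxeolitic formulation), degrees in (-180, 180].
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def _single_atom(frame: Frame, res: int, atom: str, chain: str = "*") -> np.ndarray:
    sel = select(frame, f"{chain}:{res}:{atom}")
    if sel.n_atoms == 0:
        raise ValueError(f"atom {atom} of residue {res} not found")
    if sel.n_atoms > 1:
        raise ValueError(f"ambiguous atom {atom} of residue {res}")
    return sel.coords[0]


def backbone_dihedrals(
    frame: Frame, residue: int, chain: str = "*"
) -> tuple[float, float]:
    """Backbone (φ, ψ) of a residue, IUPAC convention, degrees.

    φ = dihedral(C(i−1), N, Cα, C); ψ = dihedral(N, Cα, C, N(i+1)).
    Raises when a flanking atom is missing (chain terminus).
    """
    c_prev = _single_atom(frame, residue - 1, "C", chain)
    n = _single_atom(frame, residue, "N", chain)
    ca = _single_atom(frame, residue, "CA", chain)
    c = _single_atom(frame, residue, "C", chain)
    n_next = _single_atom(frame, residue + 1, "N", chain)
    return _dihedral(c_prev, n, ca, c), _dihedral(n, ca, c, n_next)


@dataclass(frozen=True)
class PairDistance:
    distance: float
    is_hbond: bool


def atom_pair_distance(
    frame: Frame, atom_a: str, atom_b: str, hbond_cutoff: float = 3.5
) -> PairDistance:
    """Distance (Å) between an atom and the nearest of candidate partners.

    Selections use the mini-language (e.g. ``"*:232:OG1"`` versus
    ``"*:228:O"``); when the second selection matches several atoms the
    minimum distance is taken.  ``is_hbond`` is the donor–acceptor
    heavy-atom criterion distance ≤ cutoff (default 3.5 Å).
    """
    a = select(frame, atom_a)
    b = select(frame, atom_b)
    if a.n_atoms != 1:
        raise ValueError(f"selection {atom_a!r} must match exactly one atom")
    if b.n_atoms == 0:
        raise ValueError(f"selection {atom_b!r} matched no atoms")
    d = float(np.min(np.linalg.norm(b.coords - a.coords[0], axis=1)))
    return PairDistance(distance=d, is_hbond=d <= hbond_cutoff)


# ---------------------------------------------------------------------------
# Series and distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray
    probabilities: np.ndarray
    mode: float  # centre of the most probable bin

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class DescriptorSeries:
    """Named per-frame descriptor values with units ("deg" or "A")."""

    name: str
    unit: str
    values: np.ndarray

    def summary(self) -> dict:
        v = self.values
        return {
            "name": self.name, "unit": self.unit, "n": int(len(v)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "min": float(np.min(v)), "max": float(np.max(v)),
        }

    def histogram(self, bin_width: float) -> Histogram:
        return probability_distribution(self.values, bin_width)


def probability_distribution(values: Sequence[float], bin_width: float) -> Histogram:
    """Normalized histogram with edges aligned to multiples of bin_width.

    Probabilities sum to 1; a constant series yields a single bin.  The
    reported mode is the centre of the most probable bin.  Default bin
    widths used elsewhere in the package are 2° for angles and 0.5 Å for
    distances.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty descriptor series")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = math.floor(float(v.min()) / bin_width) * bin_width
    hi = math.ceil(float(v.max()) / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    probs = counts / counts.sum()
    mode = 0.5 * (edges[np.argmax(probs)] + edges[np.argmax(probs) + 1])
    return Histogram(edges=edges, probabilities=probs, mode=float(mode))


def compute_series(
    frames: Iterable[Frame],
    func: Callable[[Frame], float],
    name: str,
    unit: str,
) -> DescriptorSeries:
    """Apply a per-frame descriptor over a trajectory."""
    values = np.array([func(f) for f in frames], dtype=float)
    if values.size == 0:
        raise ValueError("no frames")
    return DescriptorSeries(name=name, unit=unit, values=values)


# ---------------------------------------------------------------------------
# I/O — multi-model PDB (biotite) and plain coordinate CSV
# ---------------------------------------------------------------------------

def _stack_to_frames(stack) -> list[Frame]:
    import biotite.structure as struc

    if stack.stack_depth() == 0:
        raise ValueError("empty trajectory")
    frames = []
    names = np.asarray(stack.atom_name, dtype=str)
    res_num = np.asarray(stack.res_id, dtype=int)
    res_name = np.asarray(stack.res_name, dtype=str)
    chain = np.asarray(stack.chain_id, dtype=str)
    for i in range(stack.stack_depth()):
        frames.append(
            Frame(i, names.copy(), res_num.copy(), res_name.copy(),
                  chain.copy(), np.asarray(stack.coord[i], dtype=float))
        )
    return frames


def read_trajectory(path) -> list[Frame]:
    """Read frames from a multi-model PDB (or ``.csv`` coordinate table)."""
    path = str(path)
    if path.lower().endswith(".csv"):
        return frames_from_csv(path)
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(path)
    stack = pdb_file.get_structure(model=None)
    return _stack_to_frames(stack)


def write_trajectory(frames: Sequence[Frame], path) -> None:
    """Write frames as a multi-model PDB (or ``.csv`` coordinate table).

    Note the PDB format stores coordinates at 1e-3 Å precision; use the
    CSV dialect when full double precision must survive a round trip.
    """
    path = str(path)
    if path.lower().endswith(".csv"):
        frames_to_csv(frames, path)
        return
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    first = frames[0]
    n = first.n_atoms
    array = struc.AtomArray(n)
    array.atom_name = np.asarray(first.atom_name, dtype="U6")
    array.res_id = np.asarray(first.res_num, dtype=int)
    array.res_name = np.asarray(first.res_name, dtype="U5")
    array.chain_id = np.asarray(first.chain, dtype="U4")
    array.element = np.array([_element_of(str(a)) for a in first.atom_name], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack(
        [_with_coords(array, f.coords) for f in frames]
    )
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


def _with_coords(template, coords):
    arr = template.copy()
    arr.coord = np.asarray(coords, dtype=np.float32)
    return arr


def frames_to_csv(frames: Sequence[Frame], path) -> None:
    rows = []
    for f in frames:
        for i in range(f.n_atoms):
            rows.append(
                (f.frame_index, f.atom_name[i], int(f.res_num[i]),
                 f.res_name[i], f.chain[i], *f.coords[i])
            )
    pd.DataFrame(
        rows, columns=["frame", "atom", "resnum", "resname", "chain", "x", "y", "z"]
    ).to_csv(path, index=False)


def frames_from_csv(path) -> list[Frame]:
    df = pd.read_csv(path)
    required = {"frame", "atom", "resnum", "resname", "chain", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    frames = []
    for idx, sub in df.groupby("frame", sort=True):
        frames.append(
            Frame(
                int(idx),
                sub["atom"].to_numpy(str),
                sub["resnum"].to_numpy(int),
                sub["resname"].to_numpy(str),
                sub["chain"].to_numpy(str),
                sub[["x", "y", "z"]].to_numpy(float),
            )
        )
    return frames
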