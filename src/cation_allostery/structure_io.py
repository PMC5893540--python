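"""Structures and FIRST-style constraint networks.

A protonated structure is converted into a body-bar constraint network:
every atom is a rigid body; covalent bonds, the peptide bond, disulfides,
hydrogen bonds (ranked by a Mayo 12-10 potential), hydrophobic tethers and
optional cation bridges become typed multi-bar edges.  Sweeping the
hydrogen-bond energy cutoff then reproduces the dilution series on which the
rigidity analysis operates: at cutoff E_cut all hydrogen bonds weaker than
E_cut are ignored.

The Mayo potential for a donor/hydrogen/acceptor/base geometry is

    E = V0 · [5·(d0/d)^12 − 6·(d0/d)^10] · F(θ, φ)

with d the donor-acceptor distance, θ the donor-hydrogen-acceptor angle and
φ the hydrogen-acceptor-base angle.  F is the hybridization-dependent
angular factor, 1 at ideal geometry; candidate bonds failing the geometric
screen contribute no edge.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "ParseError",
    "read_structure",
    "NetworkParams",
    "ConstraintEdge",
    "ConstraintNetwork",
    "mayo_energy",
    "build_network",
    "filter_by_cutoff",
    "add_cation_bridge",
]


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    resnum: int
    resname: str
    chain: str
    x: float
    y: float
    z: float
    het: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Structure:
    """Parsed structure; `frames` holds one atom list per MODEL."""

    frames: List[List[Atom]]
    source: str = ""

    @property
    def atoms(self) -> List[Atom]:
        return self.frames[0]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, frame: int = 0) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.frames[frame]])

    def residue_numbers(self) -> List[int]:
        seen = []
        for a in self.atoms:
            if not a.het and a.resnum not in seen:
                seen.append(a.resnum)
        return seen


_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I",
    "NA", "MG", "K", "CA", "ZN", "FE", "MN", "CU", "AR",
}

METALS = {"NA", "MG", "K", "CA", "ZN", "FE", "MN", "CU"}


def _infer_element(name: str, resname: str, het: bool) -> str:
    """Element from the atom-name column when columns 77-78 are blank."""
    name = name.strip()
    if het and name.upper() in METALS and resname.strip().upper() == name.upper():
        return name.upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(source: str) -> Structure:
    """Parse a PDB file (path or literal text).

    All ATOM/HETATM records are read; MODEL/ENDMDL blocks become frames.
    Malformed ATOM records raise :class:`ParseError` naming the line; an
    unresolvable element raises naming the atom.
    """
    if "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    frames: List[List[Atom]] = []
    current: List[Atom] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current and not in_model:
                raise ParseError(f"line {lineno}: MODEL after un-closed atom block")
            in_model = True
            current = []
        elif rec == "ENDMDL":
            frames.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {lineno}: truncated {rec} record")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record ({exc})")
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(line[12:16], resname, rec == "HETATM")
            if element not in _ELEMENTS:
                raise ParseError(
                    f"line {lineno}: cannot resolve element for atom "
                    f"{name!r} in {resname} {resnum}"
                )
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ParseError(f"line {lineno}: non-finite coordinates")
            current.append(
                Atom(serial, name, element, resnum, resname, chain, x, y, z,
                     het=rec == "HETATM")
            )
    if current:
        frames.append(current)
    if not frames or not any(frames):
        raise ParseError("no ATOM/HETATM records found")
    frames = [f for f in frames if f]
    return Structure(frames=frames)


# ---------------------------------------------------------------------------
# Network parameters
# ---------------------------------------------------------------------------

COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}
VDW_RADII = {"C": 1.70, "S": 1.80}

DEFAULT_BARS = {
    "covalent": 5,
    "peptide_double": 6,
    "disulfide": 5,
    "hbond": 5,
    "saltbridge": 5,
    "hydrophobic": 2,
    "cation_bridge_ion": 6,
    "cation_bridge_lock": 6,
}


@dataclass(frozen=True)
class NetworkParams:
    """Tunable constraint-network parameters (all config-exposed).

    Mayo: V0 (kcal/mol, well depth) and d0 (Å, equilibrium donor-acceptor
    distance).  Geometric screen: maximum donor-acceptor and
    hydrogen-acceptor distances and minimum donor angle.  `lock_terminal`
    assigns six bars to bonds whose endpoint atom has covalent degree one
    (carbonyl O, hydrogens): in a body-bar model a five-bar bond to such an
    atom would leave a physically meaningless spin DOF.
    """

    mayo_v0: float = 8.0
    mayo_d0: float = 2.8
    da_max: float = 3.6
    ha_max: float = 2.6
    donor_angle_min_deg: float = 110.0
    covalent_tol: float = 0.45
    disulfide_max: float = 2.5
    hydrophobic_slack: float = 0.25
    hydrophobic_enabled: bool = True
    lock_terminal: bool = True
    bars: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BARS))

    def __post_init__(self):
        for name in ("mayo_v0", "mayo_d0", "da_max", "ha_max", "covalent_tol",
                     "disulfide_max", "hydrophobic_slack"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str) -> "NetworkParams":
        with open(path) as fh:
            return cls(**json.load(fh))


# sp2/sp3 assignment for standard amino-acid donors/acceptors; unknown -> sp3
_SP2_ATOMS = {
    ("*", "N"), ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("ASN", "ND2"), ("GLN", "OE1"), ("GLN", "NE2"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"), ("TYR", "OH"),
}


def hybridization(resname: str, atom_name: str) -> str:
    if ("*", atom_name) in _SP2_ATOMS or (resname, atom_name) in _SP2_ATOMS:
        return "sp2"
    return "sp3"


def mayo_energy(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    base: np.ndarray,
    donor_hyb: str = "sp2",
    acceptor_hyb: str = "sp2",
    params: Optional[NetworkParams] = None,
) -> float:
    """Mayo 12-10 hydrogen-bond energy in kcal/mol (0 when the screen fails).

    θ = donor-hydrogen-acceptor angle (ideal 180°); φ = hydrogen-acceptor-
    base angle with hybridization-dependent ideal value (109.5° for an sp3
    acceptor, 120° for sp2).  F = cos²θ·exp(−(π−θ)⁶)·cos²(φ−φ0) ∈ [0, 1].
    """
    p = params or NetworkParams()
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    base = np.asarray(base, float)

    d = float(np.linalg.norm(donor - acceptor))
    ha = float(np.linalg.norm(hydrogen - acceptor))
    if d <= 0 or ha <= 0:
        raise ValueError("degenerate geometry: zero distance")
    if d > p.da_max or ha > p.ha_max:
        return 0.0

    def angle(a, b, c):
        u, v = a - b, c - b
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.acos(max(-1.0, min(1.0, cosang)))

    theta = angle(donor, hydrogen, acceptor)
    if math.degrees(theta) < p.donor_angle_min_deg:
        return 0.0
    phi = angle(hydrogen, acceptor, base)
    phi0 = math.radians(109.5 if acceptor_hyb == "sp3" else 120.0)

    radial = p.mayo_v0 * (5.0 * (p.mayo_d0 / d) ** 12 - 6.0 * (p.mayo_d0 / d) ** 10)
    f_ang = (math.cos(theta) ** 2) * math.exp(-((math.pi - theta) ** 6)) * (
        math.cos(phi - phi0) ** 2
    )
    return radial * f_ang


# ---------------------------------------------------------------------------
# Constraint network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintEdge:
    i: int  # body index (0-based position in atom list)
    j: int
    type: str
    bars: int
    energy: Optional[float] = None  # kcal/mol, hbond/saltbridge only


@dataclass
class ConstraintNetwork:
    """Atoms as rigid bodies plus typed multi-bar constraints."""

    atoms: List[Atom]
    edges: List[ConstraintEdge]
    extra_bodies: int = 0  # explicit bridge ions appended after the atoms

    @property
    def n_bodies(self) -> int:
        return len(self.atoms) + self.extra_bodies

    def body_bar(self) -> Tuple[List[int], List[Tuple[int, int, int]]]:
        return list(range(self.n_bodies)), [(e.i, e.j, e.bars) for e in self.edges]

    def residue_atoms(self, resnum: int, chain: Optional[str] = None) -> List[int]:
        out = [
            idx
            for idx, a in enumerate(self.atoms)
            if a.resnum == resnum and not a.het and (chain is None or a.chain == chain)
        ]
        if not out:
            raise KeyError(f"residue {resnum} not present")
        return out

    def site_atoms(self, residues: Iterable[int], chain: Optional[str] = None) -> List[int]:
        out: List[int] = []
        for r in residues:
            out.extend(self.residue_atoms(r, chain))
        return out

    def hbond_energies(self) -> List[float]:
        return sorted(
            e.energy for e in self.edges if e.type in ("hbond", "saltbridge")
        )

    def to_tsv(self) -> str:
        lines = ["i\tj\ttype\tbars\tenergy_kcal_mol"]
        for e in self.edges:
            en = "" if e.energy is None else f"{e.energy:.6f}"
            lines.append(f"{e.i}\t{e.j}\t{e.type}\t{e.bars}\t{en}")
        return "\n".join(lines) + "\n"

    def summary(self) -> Dict[str, object]:
        counts: Dict[str, int] = {}
        for e in self.edges:
            counts[e.type] = counts.get(e.type, 0) + 1
        return {
            "n_bodies": self.n_bodies,
            "n_atoms": len(self.atoms),
            "edge_counts": counts,
            "hbond_energy_range": (
                [min(self.hbond_energies()), max(self.hbond_energies())]
                if any(e.type == "hbond" for e in self.edges)
                else None
            ),
        }


def _neighbor_pairs(coords: np.ndarray, cutoff: float):
    """All index pairs within `cutoff`, via a uniform grid (O(n))."""
    cell = max(cutoff, 1e-6)
    grid: Dict[Tuple[int, int, int], List[int]] = {}
    keys = np.floor(coords / cell).astype(int)
    for idx, key in enumerate(map(tuple, keys)):
        grid.setdefault(key, []).append(idx)
    for (cx, cy, cz), members in grid.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    other = grid.get((cx + dx, cy + dy, cz + dz))
                    if other is None:
                        continue
                    for i in members:
                        for j in other:
                            if i < j:
                                d = float(np.linalg.norm(coords[i] - coords[j]))
                                if d <= cutoff:
                                    yield i, j, d


def build_network(
    structure: Structure,
    params: Optional[NetworkParams] = None,
    frame: int = 0,
) -> ConstraintNetwork:
    """Build the constraint network for one frame of a protonated structure.

    Covalent bonds come from element-pair distance tables (covalent radii +
    tolerance, hydrogens limited to their nearest heavy atom); the peptide
    C-N bond is locked; disulfides are detected by S-S distance; every
    candidate hydrogen bond passing the geometric screen is stored with its
    Mayo energy; hydrophobic tethers connect C/S atoms of distant residues
    within vdW sum + slack.  Metal HETATMs form no covalent bonds (use
    :func:`add_cation_bridge` to couple them in).
    """
    p = params or NetworkParams()
    atoms = structure.frames[frame]
    n = len(atoms)
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    if n == 0:
        raise ValueError("empty structure")

    max_cov = max(COVALENT_RADII.values()) * 2 + p.covalent_tol
    candidate_pairs = list(_neighbor_pairs(coords, max(max_cov, p.da_max, 4.2)))

    # --- covalent bonds -----------------------------------------------------
    def cov_cutoff(ei, ej):
        ri, rj = COVALENT_RADII.get(ei), COVALENT_RADII.get(ej)
        if ri is None or rj is None:
            return None  # metals etc: no covalent bonding
        return ri + rj + p.covalent_tol

    h_best: Dict[int, Tuple[float, int]] = {}
    heavy_bonds: List[Tuple[int, int, float]] = []
    for i, j, d in candidate_pairs:
        ai, aj = atoms[i], atoms[j]
        cut = cov_cutoff(ai.element, aj.element)
        if cut is None or d > cut:
            continue
        if ai.element == "H" and aj.element == "H":
            continue
        if ai.element == "H" or aj.element == "H":
            h, heavy = (i, j) if ai.element == "H" else (j, i)
            if h not in h_best or d < h_best[h][0]:
                h_best[h] = (d, heavy)
        else:
            heavy_bonds.append((i, j, d))

    bonds: List[Tuple[int, int]] = [(i, j) for i, j, _ in heavy_bonds]
    bonds += [(min(h, heavy), max(h, heavy)) for h, (_, heavy) in h_best.items()]
    bonds = sorted(set(bonds))

    degree = [0] * n
    adjacency: Dict[int, set] = {i: set() for i in range(n)}
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
        adjacency[i].add(j)
        adjacency[j].add(i)

    missing_h = not any(a.element == "H" for a in atoms)
    edges: List[ConstraintEdge] = []
    for i, j in bonds:
        ai, aj = atoms[i], atoms[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if ai.element == "S" and aj.element == "S" and d <= p.disulfide_max:
            etype, bars = "disulfide", p.bars["disulfide"]
        elif (
            {ai.name, aj.name} == {"C", "N"}
            and not ai.het
            and not aj.het
            and ai.resnum != aj.resnum
        ):
            etype, bars = "peptide_double", p.bars["peptide_double"]
        else:
            etype, bars = "covalent", p.bars["covalent"]
            if p.lock_terminal and (degree[i] == 1 or degree[j] == 1):
                bars = 6
        edges.append(ConstraintEdge(i, j, etype, bars))

    # --- hydrogen bonds -----------------------------------------------------
    if not missing_h:
        donors = []  # (h_idx, donor_idx)
        for h, (_, heavy) in h_best.items():
            if atoms[heavy].element in ("N", "O", "S"):
                donors.append((h, heavy))
        acceptors = []
        for idx, a in enumerate(atoms):
            if a.element in ("N", "O", "S") and not a.het:
                bases = [b for b in adjacency[idx] if atoms[b].element != "H"]
                if bases:
                    acceptors.append((idx, min(bases)))
        for h, d_idx in sorted(donors):
            for a_idx, b_idx in acceptors:
                if a_idx in (h, d_idx) or a_idx in adjacency[d_idx] or a_idx in adjacency[h]:
                    continue
                e = mayo_energy(
                    coords[d_idx], coords[h], coords[a_idx], coords[b_idx],
                    hybridization(atoms[d_idx].resname, atoms[d_idx].name),
                    hybridization(atoms[a_idx].resname, atoms[a_idx].name),
                    p,
                )
                if e < 0:
                    edges.append(
                        ConstraintEdge(min(h, a_idx), max(h, a_idx), "hbond",
                                       p.bars["hbond"], energy=float(e))
                    )

    # --- hydrophobic tethers -------------------------------------------------
    # only apolar carbons/sulfurs tether: atoms covalently bonded to N or O
    # (backbone CA, carbonyl/carboxylate carbons) are excluded
    if p.hydrophobic_enabled:
        def apolar(idx):
            a = atoms[idx]
            if a.element not in VDW_RADII or a.het:
                return False
            return not any(atoms[b].element in ("N", "O") for b in adjacency[idx])

        for i, j, d in candidate_pairs:
            ai, aj = atoms[i], atoms[j]
            if abs(ai.resnum - aj.resnum) < 2:
                continue
            if not (apolar(i) and apolar(j)) or j in adjacency[i]:
                continue
            if d <= VDW_RADII[ai.element] + VDW_RADII[aj.element] + p.hydrophobic_slack:
                edges.append(ConstraintEdge(i, j, "hydrophobic", p.bars["hydrophobic"]))

    edges.sort(key=lambda e: (e.i, e.j, e.type))
    return ConstraintNetwork(atoms=list(atoms), edges=edges)


def filter_by_cutoff(network: ConstraintNetwork, e_cut: float) -> ConstraintNetwork:
    """Retain hbond/saltbridge edges with energy ≤ E_cut (i.e. at least that
    strong); all other edge types pass through.  Input is not modified."""
    if e_cut > 0:
        raise ValueError("energy cutoff must be <= 0 kcal/mol")
    kept = [
        e
        for e in network.edges
        if e.type not in ("hbond", "saltbridge") or (e.energy is not None and e.energy <= e_cut)
    ]
    return ConstraintNetwork(
        atoms=network.atoms, edges=kept, extra_bodies=network.extra_bodies
    )


def add_cation_bridge(
    network: ConstraintNetwork,
    coordinating_atoms: Sequence[int],
    mode: str = "explicit_ion",
) -> ConstraintNetwork:
    """Rigidify a divalent-cation bridge between coordinating atoms.

    `explicit_ion` appends one new body (the cation) bonded to each
    coordinating atom; `direct_lock` adds a locked edge from the first
    coordinating atom to each of the others.  Bridge edges are typed
    `cation_bridge` and are never removed by the energy-cutoff filter.
    """
    atoms = list(coordinating_atoms)
    if len(atoms) < 2:
        raise ValueError("a cation bridge needs at least 2 coordinating atoms")
    for a in atoms:
        if not 0 <= a < network.n_bodies:
            raise ValueError(f"coordinating atom index {a} out of range")
    edges = list(network.edges)
    p_bars = DEFAULT_BARS
    if mode == "explicit_ion":
        ion = network.n_bodies
        for a in sorted(atoms):
            edges.append(
                ConstraintEdge(a, ion, "cation_bridge", p_bars["cation_bridge_ion"])
            )
        return ConstraintNetwork(
            atoms=network.atoms, edges=edges, extra_bodies=network.extra_bodies + 1
        )
    if mode == "direct_lock":
        first = atoms[0]
        for a in atoms[1:]:
            i, j = min(first, a), max(first, a)
            edges.append(
                ConstraintEdge(i, j, "cation_bridge", p_bars["cation_bridge_lock"])
            )
        return ConstraintNetwork(
            atoms=network.atoms, edges=edges, extra_bodies=network.extra_bodies
        )
    raise ValueError("mode must be explicit_ion or direct_lock")
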