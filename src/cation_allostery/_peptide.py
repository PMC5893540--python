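"""Minimal internal-coordinate peptide construction.

Builds idealized polypeptide geometry (canonical bond lengths and angles,
caller-supplied φ/ψ/χ dihedrals, trans peptide bonds) with the natural
extension reference frame.  Only the residue types the toy-receptor fixture
needs are implemented: GLY, ALA, SER, CYS, ASP, GLU.  Geometry is idealized
rather than energy-minimized — sufficient for constraint detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

# canonical backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O, A_C_N_H = 121.7, 111.2, 116.2, 120.8, 119.5
OMEGA = 180.0


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position d with |d−c| = bond, ∠(b,c,d) = angle, dihedral(a,b,c,d)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear reference: pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, bc)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    M = np.column_stack([bc, m, n])
    return c + M @ d2


@dataclass
class ResidueSpec:
    name: str
    phi: float
    psi: float
    chi: Tuple[float, ...] = ()


@dataclass
class BuiltAtom:
    name: str
    element: str
    resnum: int
    resname: str
    pos: np.ndarray


def _sidechain(res: ResidueSpec, N, CA, C) -> List[Tuple[str, str, np.ndarray]]:
    """Side-chain atoms as (name, element, pos); idealized rotamers."""
    out: List[Tuple[str, str, np.ndarray]] = []
    if res.name == "GLY":
        return out
    CB = place_atom(N, C, CA, 1.53, 110.5, 122.5)
    out.append(("CB", "C", CB))
    chi = list(res.chi) + [180.0] * 3
    if res.name == "ALA":
        return out
    if res.name == "CYS":
        out.append(("SG", "S", place_atom(N, CA, CB, 1.81, 114.0, chi[0])))
    elif res.name == "SER":
        OG = place_atom(N, CA, CB, 1.41, 110.5, chi[0])
        out.append(("OG", "O", OG))
        out.append(("HG", "H", place_atom(CA, CB, OG, 0.96, 109.0, chi[1])))
    elif res.name == "ASP":
        CG = place_atom(N, CA, CB, 1.52, 114.0, chi[0])
        out.append(("CG", "C", CG))
        out.append(("OD1", "O", place_atom(CA, CB, CG, 1.25, 118.0, chi[1])))
        out.append(("OD2", "O", place_atom(CA, CB, CG, 1.25, 118.0, chi[1] + 180.0)))
    elif res.name == "GLU":
        CG = place_atom(N, CA, CB, 1.52, 114.0, chi[0])
        out.append(("CG", "C", CG))
        CD = place_atom(CA, CB, CG, 1.52, 114.0, chi[1])
        out.append(("CD", "C", CD))
        out.append(("OE1", "O", place_atom(CB, CG, CD, 1.25, 118.0, chi[2])))
        out.append(("OE2", "O", place_atom(CB, CG, CD, 1.25, 118.0, chi[2] + 180.0)))
    else:
        raise ValueError(f"unsupported residue type {res.name}")
    return out


def build_chain(residues: Sequence[ResidueSpec]) -> List[BuiltAtom]:
    """Construct the full-atom chain (N, H, CA, C, O + side chain)."""
    atoms: List[BuiltAtom] = []
    prev = None  # (N, CA, C, O) of the preceding residue
    for i, res in enumerate(residues):
        num = i + 1
        if i == 0:
            N = np.zeros(3)
            CA = np.array([B_N_CA, 0.0, 0.0])
            C = place_atom(np.array([0.0, 1.0, 0.0]), N, CA, B_CA_C, A_N_CA_C, res.phi)
            H = place_atom(C, CA, N, B_N_H, 118.0, 180.0)
        else:
            pN, pCA, pC, pO = prev
            N = place_atom(pN, pCA, pC, B_C_N, A_CA_C_N, residues[i - 1].psi)
            CA = place_atom(pCA, pC, N, B_N_CA, A_C_N_CA, OMEGA)
            C = place_atom(pC, N, CA, B_CA_C, A_N_CA_C, res.phi)
            # trans amide H: anti to the preceding carbonyl O
            H = place_atom(pO, pC, N, B_N_H, A_C_N_H, 180.0)
        O = place_atom(N, CA, C, B_C_O, A_CA_C_O, res.psi + 180.0)
        atoms.append(BuiltAtom("N", "N", num, res.name, N))
        atoms.append(BuiltAtom("H", "H", num, res.name, H))
        atoms.append(BuiltAtom("CA", "C", num, res.name, CA))
        for name, elem, pos in _sidechain(res, N, CA, C):
            atoms.append(BuiltAtom(name, elem, num, res.name, pos))
        atoms.append(BuiltAtom("C", "C", num, res.name, C))
        atoms.append(BuiltAtom("O", "O", num, res.name, O))
        prev = (N, CA, C, O)
    return atoms


def to_pdb(atoms: Sequence[BuiltAtom], chain: str = "A") -> str:
    lines = []
    for serial, a in enumerate(atoms, start=1):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name}{a.resname:>4s} {chain}{a.resnum:4d}    "
            f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}  1.00  0.00"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


_PEPTIDE_LINK = {"CA", "C", "O"}  # last-residue side of the junction
_PEPTIDE_NEXT = {"N", "H", "CA", "C"}  # first-residue side


def min_nonbonded_distance(atoms: Sequence[BuiltAtom]) -> float:
    """Smallest through-space distance between atoms not covalently close.

    Same-residue pairs are excluded (internal geometry is fixed by
    construction), as are the ≤4-bond backbone pairs across a peptide
    junction.  Everything else counts, including intended hydrogen-bond
    contacts (≈2 Å H···O), so a clash threshold should sit below those.
    """
    coords = np.array([a.pos for a in atoms])
    n = len(atoms)
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj = atoms[i], atoms[j]
            if ai.resnum == aj.resnum:
                continue
            if (
                aj.resnum - ai.resnum == 1
                and ai.name in _PEPTIDE_LINK
                and aj.name in _PEPTIDE_NEXT
            ):
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < best:
                best = d
    return best
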