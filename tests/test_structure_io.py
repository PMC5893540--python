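"""PDB parsing, the Mayo potential, and constraint-network construction."""

import math

import numpy as np
import pytest

from cation_allostery import fixtures, pebble, structure_io as sio


# --- parsing ----------------------------------------------------------------

def test_multi_model_parsing():
    txt = fixtures.gen_ion_trajectory(3, [fixtures.IonPath(residue=1, distance_nm=0.3)])
    st = sio.read_structure(txt)
    assert st.n_frames == 3


def test_truncated_record_raises_with_line_number():
    bad = "ATOM      1  CA  GLY A   1      1.000\nEND\n"
    with pytest.raises(sio.ParseError, match="line 1"):
        sio.read_structure(bad)


def test_unknown_element_raises():
    bad = ("ATOM      1  XX  GLY A   1       0.000   0.000   0.000"
           "  1.00  0.00          XQ\nEND\n")
    with pytest.raises(sio.ParseError, match="element"):
        sio.read_structure(bad)


# --- Mayo potential ---------------------------------------------------------

def _ideal_geometry(d, phi0_deg=120.0):
    """Collinear D-H...A with the acceptor base at the ideal phi."""
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    acceptor = np.array([d, 0.0, 0.0])
    ang = math.radians(180.0 - phi0_deg)
    base = acceptor + 1.25 * np.array([math.cos(ang), math.sin(ang), 0.0])
    return donor, hydrogen, acceptor, base


def test_mayo_minimum_is_minus_v0():
    p = sio.NetworkParams()
    e = sio.mayo_energy(*_ideal_geometry(p.mayo_d0), "sp2", "sp2", p)
    assert e == pytest.approx(-p.mayo_v0, rel=1e-9)


def test_mayo_zero_crossing_at_analytic_distance():
    p = sio.NetworkParams()
    d = p.mayo_d0 * math.sqrt(5.0 / 6.0)
    e = sio.mayo_energy(*_ideal_geometry(d), "sp2", "sp2", p)
    assert e == pytest.approx(0.0, abs=1e-9)


def test_mayo_screen_rejects_long_and_bent_bonds():
    p = sio.NetworkParams()
    assert sio.mayo_energy(*_ideal_geometry(5.0), "sp2", "sp2", p) == 0.0
    # bent donor angle below the screen
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    acceptor = hydrogen + 1.8 * np.array([math.cos(math.radians(80)),
                                          math.sin(math.radians(80)), 0.0])
    base = acceptor + np.array([0.0, 1.25, 0.0])
    assert sio.mayo_energy(donor, hydrogen, acceptor, base, "sp2", "sp2", p) == 0.0


# --- network construction ---------------------------------------------------

def test_isolated_noble_atoms_make_empty_network():
    txt = ("ATOM      1  AR  ARG A   1       0.000   0.000   0.000"
           "  1.00  0.00          AR\n"
           "ATOM      2  AR  ARG A   2      20.000   0.000   0.000"
           "  1.00  0.00          AR\nEND\n")
    net = sio.build_network(sio.read_structure(txt))
    assert net.n_bodies == 2 and len(net.edges) == 0


def test_toy_receptor_hbonds_match_direct_mayo_evaluation(toy_structure, toy_network):
    """Each detected hydrogen-bond energy equals mayo_energy re-evaluated on
    the stored geometry; the sorted list is reproducible."""
    atoms = toy_network.atoms
    params = sio.NetworkParams()
    adjacency = {}
    for e in toy_network.edges:
        if e.type in ("covalent", "peptide_double", "disulfide"):
            adjacency.setdefault(e.i, set()).add(e.j)
            adjacency.setdefault(e.j, set()).add(e.i)
    for e in toy_network.edges:
        if e.type != "hbond":
            continue
        h, a = (e.i, e.j) if atoms[e.i].element == "H" else (e.j, e.i)
        donor = next(iter(adjacency[h]))
        base = min(b for b in adjacency[a] if atoms[b].element != "H")
        expect = sio.mayo_energy(
            atoms[donor].pos, atoms[h].pos, atoms[a].pos, atoms[base].pos,
            sio.hybridization(atoms[donor].resname, atoms[donor].name),
            sio.hybridization(atoms[a].resname, atoms[a].name),
            params,
        )
        assert e.energy == pytest.approx(expect, abs=1e-12)
        assert e.energy < 0
    assert toy_network.hbond_energies() == sorted(
        e.energy for e in toy_network.edges if e.type == "hbond"
    )


def test_network_invariant_under_rigid_motion(toy_structure):
    """Rotation + translation of all coordinates leaves the edge set and
    energies unchanged to 1e-9."""
    st = toy_structure
    theta = 0.7
    R = np.array([
        [math.cos(theta), -math.sin(theta), 0.0],
        [math.sin(theta), math.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    shift = np.array([5.0, -3.0, 11.0])
    moved = sio.Structure(frames=[[
        sio.Atom(a.serial, a.name, a.element, a.resnum, a.resname, a.chain,
                 *(R @ a.pos + shift), het=a.het)
        for a in st.atoms
    ]])
    n1 = sio.build_network(st)
    n2 = sio.build_network(moved)
    key = lambda n: [(e.i, e.j, e.type, e.bars) for e in n.edges]
    assert key(n1) == key(n2)
    for e1, e2 in zip(n1.edges, n2.edges):
        if e1.energy is not None:
            assert e2.energy == pytest.approx(e1.energy, abs=1e-9)


def test_filter_by_cutoff_threshold_and_monotonicity(toy_network):
    energies = toy_network.hbond_energies()
    all_kept = sio.filter_by_cutoff(toy_network, 0.0)
    assert len(all_kept.hbond_energies()) == len(energies)
    none_kept = sio.filter_by_cutoff(toy_network, min(energies) - 0.1)
    assert len(none_kept.hbond_energies()) == 0
    mid = energies[len(energies) // 2]
    some = sio.filter_by_cutoff(toy_network, mid)
    assert len(some.hbond_energies()) == sum(1 for e in energies if e <= mid)
    # monotone nesting
    prev = set()
    for cut in sorted(energies) + [0.0]:
        kept = set(sio.filter_by_cutoff(toy_network, cut).hbond_energies())
        assert prev <= kept
        prev = kept
    # input untouched
    assert len(toy_network.hbond_energies()) == len(energies)


def test_synthetic_threshold_counting():
    atoms = [sio.Atom(i + 1, "X", "C", i + 1, "GLY", "A", float(i), 0, 0)
             for i in range(4)]
    edges = [
        sio.ConstraintEdge(0, 1, "hbond", 5, energy=-1.0),
        sio.ConstraintEdge(1, 2, "hbond", 5, energy=-3.0),
        sio.ConstraintEdge(2, 3, "hbond", 5, energy=-5.0),
    ]
    net = sio.ConstraintNetwork(atoms=atoms, edges=edges)
    assert len(sio.filter_by_cutoff(net, -2.0).edges) == 2


def test_add_cation_bridge_modes(toy_network, bridge_atoms):
    i, j = bridge_atoms
    ion = sio.add_cation_bridge(toy_network, [i, j], "explicit_ion")
    assert ion.n_bodies == toy_network.n_bodies + 1
    assert len(ion.edges) == len(toy_network.edges) + 2
    lock = sio.add_cation_bridge(toy_network, [i, j], "direct_lock")
    assert lock.n_bodies == toy_network.n_bodies
    assert len(lock.edges) == len(toy_network.edges) + 1
    with pytest.raises(ValueError):
        sio.add_cation_bridge(toy_network, [i], "direct_lock")


def test_bridge_strictly_reduces_total_dof(toy_network, bridge_atoms):
    base = pebble.build_game(toy_network).total_dof()
    bridged = sio.add_cation_bridge(toy_network, list(bridge_atoms), "explicit_ion")
    assert pebble.build_game(bridged).total_dof() < base
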