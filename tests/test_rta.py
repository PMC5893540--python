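"""Rigidity-transmission allostery: DOF_AB formula, sweeps, window scans and
bridge perturbation."""

import numpy as np
import pytest

from cation_allostery import fixtures, pebble, rta, structure_io as sio
from conftest import random_framework

SWEEP = (0.0, -6.0, 0.05)  # coarse but breakpoint-equivalent for unit tests


def test_rigid_pair_transmits_nothing():
    fw = fixtures.gen_framework(fixtures.FrameworkSpec(template="rigid_pair"))
    tp = rta.transmitted_dof(fw, [0], [1])
    assert (tp.a_max, tp.b_max, tp.ab_max) == (6, 6, 6)
    assert tp.dof_ab_raw == 0 and tp.dof_ab == 0


def test_disconnected_bodies_report_clamped_zero():
    fw = fixtures.Framework(bodies=[0, 1], edges=[])
    tp = rta.transmitted_dof(fw, [0], [1])
    assert tp.dof_ab_raw == -6
    assert tp.dof_ab == 0


def test_coupled_hinges_transmit_one_dof_matching_oracle():
    fw = fixtures.gen_framework(fixtures.FrameworkSpec(template="coupled_hinges"))
    a, b = [0, 1], [2, 3]
    tp = rta.transmitted_dof(fw, a, b)
    oracle = (
        pebble.oracle_dof(fw, a, seed=2)
        + pebble.oracle_dof(fw, b, seed=2)
        - pebble.oracle_dof(fw, a + b, seed=2)
        - 6
    )
    assert tp.dof_ab_raw == oracle == 1


def test_transmitted_dof_symmetric_and_bounded_on_random_frameworks():
    for seed in range(20):
        fw = random_framework(seed, n=8)
        a, b = [0, 1], [6, 7]
        t1 = rta.transmitted_dof(fw, a, b)
        t2 = rta.transmitted_dof(fw, b, a)
        assert t1.dof_ab_raw == t2.dof_ab_raw
        assert t1.dof_ab <= (t1.a_max - 6) + (t1.b_max - 6)
        assert t1.dof_ab <= 6 * min(len(a), len(b))
        oracle = (
            pebble.oracle_dof(fw, a, seed=seed)
            + pebble.oracle_dof(fw, b, seed=seed)
            - pebble.oracle_dof(fw, a + b, seed=seed)
            - 6
        )
        assert t1.dof_ab_raw == oracle


def test_overlapping_sites_rejected():
    fw = random_framework(1, n=5)
    with pytest.raises(ValueError):
        rta.transmitted_dof(fw, [0, 1], [1, 2])


def test_sweep_grid_point_count(toy_network):
    site_a = toy_network.site_atoms([15])
    site_b = toy_network.site_atoms([2])
    prof = rta.transmission_curve(toy_network, site_a, site_b, (0.0, -6.0, 0.01))
    assert len(prof.points) == 601
    assert prof.points[0].e_cut == pytest.approx(0.0)
    assert prof.points[-1].e_cut == pytest.approx(-6.0)


def _flat_network():
    """Coupled-hinges topology as an atom network with no hydrogen bonds:
    the transmission curve must be flat at 1 across any sweep."""
    fw = fixtures.gen_framework(fixtures.FrameworkSpec(template="coupled_hinges"))
    atoms = [sio.Atom(i + 1, "X", "C", i + 1, "GLY", "A", float(i), 0, 0)
             for i in range(4)]
    return sio.ConstraintNetwork(
        atoms=atoms,
        edges=[sio.ConstraintEdge(u, v, "covalent", m) for u, v, m in fw.edges],
    )


def test_curve_flat_without_hbonds():
    prof = rta.transmission_curve(_flat_network(), [0, 1], [2, 3], SWEEP)
    assert {p.dof_ab for p in prof.points} == {1}


def test_intensity_rectangle_rule():
    prof = rta.transmission_curve(_flat_network(), [0, 1], [2, 3], (0.0, -2.0, 0.1))
    # constant dof_ab = 1 across 21 grid points of width 0.1
    assert rta.intensity(prof) == pytest.approx(1 * 0.1 * 21)


def test_intensity_zero_for_all_zero_curve():
    fw = fixtures.gen_framework(fixtures.FrameworkSpec(template="rigid_pair"))
    atoms = [sio.Atom(i + 1, "X", "C", i + 1, "GLY", "A", float(i), 0, 0)
             for i in range(2)]
    net = sio.ConstraintNetwork(
        atoms=atoms, edges=[sio.ConstraintEdge(0, 1, "covalent", 6)]
    )
    prof = rta.transmission_curve(net, [0], [1], SWEEP)
    assert rta.intensity(prof) == 0.0


def test_intensity_refinement_stability(toy_network, bridge_atoms):
    """Halving the sweep step changes the Riemann sum by at most one
    coarse-step width times the curve maximum."""
    bridged = sio.add_cation_bridge(toy_network, list(bridge_atoms), "explicit_ion")
    a = bridged.site_atoms([15, 16, 17])
    b = bridged.site_atoms([1, 2, 3])
    coarse = rta.transmission_curve(bridged, a, b, (0.0, -6.0, 0.04))
    fine = rta.transmission_curve(bridged, a, b, (0.0, -6.0, 0.02))
    max_dof = max(p.dof_ab for p in coarse.points)
    assert abs(rta.intensity(coarse) - rta.intensity(fine)) <= 0.04 * max(max_dof, 1) * (
        len(toy_network.hbond_energies()) + 1
    )


def test_window_intensity_averaging_rules(toy_network):
    res = rta.window_scan(toy_network, (14, 18), (1, 2, 3), SWEEP)
    w = res.window_intensity
    # interior residue 16 is in all three windows
    expect_16 = np.mean([w[(14, 15, 16)], w[(15, 16, 17)], w[(16, 17, 18)]])
    assert res.residue_intensity[16] == pytest.approx(expect_16)
    # first residue of the range appears in exactly one window
    assert res.residue_intensity[14] == pytest.approx(w[(14, 15, 16)])
    # second residue in two windows
    expect_15 = np.mean([w[(14, 15, 16)], w[(15, 16, 17)]])
    assert res.residue_intensity[15] == pytest.approx(expect_15)


def test_window_scan_deterministic(toy_network):
    a = rta.window_scan(toy_network, (14, 18), (1, 2, 3), SWEEP)
    b = rta.window_scan(toy_network, (14, 18), (1, 2, 3), SWEEP)
    assert a.residue_intensity == b.residue_intensity


def test_window_scan_invariant_under_consistent_renumbering(toy_structure):
    shifted = sio.Structure(frames=[[
        sio.Atom(a.serial, a.name, a.element, a.resnum + 100, a.resname,
                 a.chain, a.x, a.y, a.z, het=a.het)
        for a in toy_structure.atoms
    ]])
    n1 = sio.build_network(toy_structure)
    n2 = sio.build_network(shifted)
    r1 = rta.window_scan(n1, (14, 18), (1, 2, 3), SWEEP)
    r2 = rta.window_scan(n2, (114, 118), (101, 102, 103), SWEEP)
    assert list(r1.residue_intensity.values()) == list(r2.residue_intensity.values())


def test_scan_range_overlap_with_sink_rejected(toy_network):
    with pytest.raises(ValueError):
        rta.window_scan(toy_network, (1, 5), (1, 2, 3), SWEEP)


def test_bridge_raises_intensity_and_lowers_none(toy, toy_network, bridge_atoms):
    cmp = rta.bridge_comparison(
        toy_network,
        [rta.BridgeSpec(atoms=tuple(bridge_atoms), mode="explicit_ion")],
        toy.scan_range, toy.sink_residues, SWEEP,
    )
    deltas = list(cmp.delta.values())
    assert max(deltas) > 0
    assert min(deltas) >= -1e-12


def test_bridge_between_corigid_atoms_changes_nothing(toy_network):
    """Locking two atoms that already share a rigid cluster is redundant."""
    dec = pebble.decompose(toy_network)
    pair = None
    for e in toy_network.edges:
        if e.bars == 6 and dec.labels[e.i] == dec.labels[e.j]:
            pair = (e.i, e.j)
            break
    assert pair is not None
    bridged = sio.add_cation_bridge(toy_network, list(pair), "direct_lock")
    a = toy_network.site_atoms([15, 16])
    b = toy_network.site_atoms([1, 2])
    t1 = rta.transmitted_dof(toy_network, a, b)
    t2 = rta.transmitted_dof(bridged, a, b)
    assert t1.dof_ab_raw == t2.dof_ab_raw


def test_direct_lock_and_explicit_ion_agree_on_bridged_clusters(toy_network, bridge_atoms):
    i, j = bridge_atoms
    lock = sio.add_cation_bridge(toy_network, [i, j], "direct_lock")
    ion = sio.add_cation_bridge(toy_network, [i, j], "explicit_ion")
    dec_lock = pebble.decompose(lock)
    dec_ion = pebble.decompose(ion)
    # bridged atoms are co-rigid under both realizations
    assert dec_lock.labels[i] == dec_lock.labels[j]
    assert dec_ion.labels[i] == dec_ion.labels[j]
    # atom-level cluster partitions agree (ignore the extra ion body)
    def partition(dec, n):
        groups = {}
        for body in range(n):
            groups.setdefault(dec.labels[body], []).append(body)
        return sorted(map(tuple, groups.values()))
    n = len(toy_network.atoms)
    assert partition(dec_lock, n) == partition(dec_ion, n)
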