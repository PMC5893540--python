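"""Generators: determinism, noiseless exactness, and input validation."""

import numpy as np
import pandas as pd
import pytest

from cation_allostery import binding, fixtures, nmr, structure_io as sio


def test_framework_spec_validation():
    with pytest.raises(ValueError):
        fixtures.FrameworkSpec(template="nonsense")
    with pytest.raises(ValueError):
        fixtures.FrameworkSpec(template="rigid_pair", n_bodies=0)
    with pytest.raises(ValueError):
        fixtures.FrameworkSpec(template="rigid_pair", bars_per_edge=7)
    with pytest.raises(ValueError):
        fixtures.FrameworkSpec(template="random", n_bodies=51)


def test_random_framework_deterministic():
    spec = fixtures.FrameworkSpec(template="random", n_bodies=12, seed=5)
    a, b = fixtures.gen_framework(spec), fixtures.gen_framework(spec)
    assert a.bodies == b.bodies and a.edges == b.edges


def test_toy_receptor_deterministic_and_valid(toy):
    again = fixtures.gen_toy_receptor(seed=toy.params.seed)
    assert again.pdb_text == toy.pdb_text
    assert toy.n_atoms <= 300
    st = sio.read_structure(toy.pdb_text)
    assert len(st.atoms) == toy.n_atoms


def test_toy_receptor_bridge_oxygens_close(toy, toy_structure):
    pos = {(a.resnum, a.name): a.pos for a in toy_structure.atoms}
    (r1, o1), (r2, o2) = toy.bridge_atoms
    assert np.linalg.norm(pos[(r1, o1)] - pos[(r2, o2)]) <= 5.0


def test_toy_receptor_network_features(toy_network):
    hb = toy_network.hbond_energies()
    assert len(hb) >= 6
    assert all(e < 0 for e in hb)
    assert max(hb) - min(hb) > 1.0  # graded energy range
    assert sum(1 for e in toy_network.edges if e.type == "disulfide") == 1


@pytest.mark.parametrize(
    "model,truth,design,col",
    [
        ("linewidth_isotherm", {"kd_mM": 61.0, "amplitude": 150.0},
         {"conc_mM": [10, 61.0, 500]}, "linewidth_Hz"),
        ("saturation", {"bmax": 50.0, "kd_nM": 5.0, "ns": 0.1},
         {"conc_nM": [1, 5, 20, 100]}, "bound"),
        ("dose_response", {"e0": 10.0, "emax": 80.0, "ec50_uM": 375.0},
         {"conc_uM": [10, 100, 375, 1000, 5000]}, "response"),
    ],
)
def test_noiseless_curves_lie_on_forward_model(model, truth, design, col):
    spec = fixtures.SyntheticCurveSpec(model=model, truth=truth, design=design,
                                       noise=0.0, seed=0)
    df = fixtures.gen_curve(spec)
    x = df.iloc[:, 0].to_numpy()
    if model == "linewidth_isotherm":
        y = nmr.hyperbola(x, truth["amplitude"], truth["kd_mM"])
        # hyperbola midpoint identity
        assert df.loc[df["conc_mM"] == 61.0, col].iloc[0] == pytest.approx(75.0)
    elif model == "saturation":
        y = binding.saturation_forward(x, truth["bmax"], truth["kd_nM"], truth["ns"])
    else:
        y = binding.dose_response_forward(x, truth["e0"], truth["emax"], truth["ec50_uM"])
    np.testing.assert_allclose(df[col].to_numpy(), y, rtol=1e-12)


def test_curve_seed_determinism_and_noise():
    spec = dict(model="linewidth_isotherm", truth={"kd_mM": 61.0, "amplitude": 150.0},
                design={"conc_mM": [10, 50, 200, 800]})
    a = fixtures.gen_curve(fixtures.SyntheticCurveSpec(**spec, noise=0.05, seed=3))
    b = fixtures.gen_curve(fixtures.SyntheticCurveSpec(**spec, noise=0.05, seed=3))
    c = fixtures.gen_curve(fixtures.SyntheticCurveSpec(**spec, noise=0.05, seed=4))
    pd.testing.assert_frame_equal(a, b)
    assert not np.allclose(a["linewidth_Hz"], c["linewidth_Hz"])


def test_cpmg_curve_fast_pulsing_limit():
    truth = {"p_b": 3e-4, "tau_b_s": 480e-6, "dw_ref_rad_s": 2e4,
             "ref_field_MHz": 158.7, "r2_0_s1": 22.0}
    k_ex = (1 / 480e-6) / (1 - 3e-4)
    spec = fixtures.SyntheticCurveSpec(
        model="cpmg_dispersion", truth=truth,
        design={"fields_MHz": [158.7], "nu_cpmg_Hz": [10 * k_ex]},
        noise=0.0, seed=0)
    df = fixtures.gen_curve(spec)
    assert df["R2eff_s1"].iloc[0] == pytest.approx(22.0, rel=0.01)


def test_curve_rejects_invalid_truth_and_design():
    with pytest.raises(ValueError):
        fixtures.gen_curve(fixtures.SyntheticCurveSpec(
            model="linewidth_isotherm", truth={"kd_mM": -1.0, "amplitude": 1.0},
            design={"conc_mM": [1, 2, 3]}))
    with pytest.raises(ValueError):
        fixtures.gen_curve(fixtures.SyntheticCurveSpec(
            model="linewidth_isotherm", truth={"kd_mM": 1.0, "amplitude": 1.0},
            design={"conc_mM": [0.0, 2, 3]}))
    with pytest.raises(ValueError):
        fixtures.SyntheticCurveSpec(model="linewidth_isotherm", truth={},
                                    design={}, noise=-0.1)


def test_ion_trajectory_scripted_contacts_roundtrip():
    txt = fixtures.gen_ion_trajectory(4, [fixtures.IonPath(residue=2, distance_nm=0.25)])
    st = sio.read_structure(txt)
    assert st.n_frames == 4
    with pytest.raises(ValueError):
        fixtures.gen_ion_trajectory(0, [fixtures.IonPath(residue=1, distance_nm=0.2)])
    with pytest.raises(ValueError):
        fixtures.gen_ion_trajectory(3, [])
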