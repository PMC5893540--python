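"""Deterministic generators for every synthetic input the pipeline needs.

Four families of fixtures:

* body-bar frameworks with oracle-known degrees of freedom (templates with
  documented ground truth plus seeded random graphs);
* a toy protonated "receptor" peptide with a hydrogen-bond ladder, a
  disulfide, an acidic bridge pair and designated G-protein-site residues;
* synthetic curves for every forward model fitted downstream (Lorentzian
  mixtures, hyperbolic isotherms, CPMG dispersions, binding curves);
* scripted multi-model ion "trajectories" with exactly known contact
  fractions.

Every generator takes an explicit seed and uses its own
:class:`numpy.random.Generator`; identical spec + seed reproduces identical
output byte-for-byte.  Noise is multiplicative Gaussian on y, matching the
relative-error character of NMR intensities and binding counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import math

import numpy as np
import pandas as pd

from . import nmr, binding

Edge = Tuple[int, int, int]

FRAMEWORK_TEMPLATES = (
    "free_body",
    "rigid_pair",
    "hinge_chain",
    "coupled_hinges",
    "two_blocks_bridged",
    "random",
)


@dataclass(frozen=True)
class FrameworkSpec:
    """Recipe for a body-bar test framework.

    ``bars_per_edge`` overrides the per-template default multiplicity where a
    template has a single natural edge class (ignored by `random`, which draws
    its own multiplicities).
    """

    template: str = "rigid_pair"
    n_bodies: int = 2
    bars_per_edge: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.template not in FRAMEWORK_TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.n_bodies < 1:
            raise ValueError("n_bodies must be >= 1")
        if self.bars_per_edge is not None and not 1 <= self.bars_per_edge <= 6:
            raise ValueError("bars_per_edge must lie in 1..6")
        if self.template == "random" and self.n_bodies > 50:
            raise ValueError("random template limited to n_bodies <= 50")


@dataclass
class Framework:
    """A body-bar multigraph plus, where known, its ground-truth DOF."""

    bodies: List[int]
    edges: List[Edge]
    truth_dof: Optional[int] = None

    def body_bar(self):
        return list(self.bodies), list(self.edges)


def gen_framework(spec: FrameworkSpec) -> Framework:
    """Instantiate a framework template.

    Ground-truth total DOF per template (n = n_bodies, 6 rigid-body motions
    always included):

    ==================  =========================================
    free_body           one body, no edges: 6
    rigid_pair          two bodies, one 6-bar edge: 6
    hinge_chain         chain of n bodies, 5-bar links: 6 + (n-1)
    coupled_hinges      two cross-linked hinged pairs: 7
    two_blocks_bridged  two rigid 3-body blocks + 1 bar: 11
    random              seeded G(n, p) with random multiplicities
                        (no closed form; oracle-checked)
    ==================  =========================================
    """
    t = spec.template
    if t == "free_body":
        return Framework(bodies=[0], edges=[], truth_dof=6)
    if t == "rigid_pair":
        m = spec.bars_per_edge or 6
        truth = 6 + (6 - m)
        return Framework(bodies=[0, 1], edges=[(0, 1, m)], truth_dof=truth)
    if t == "hinge_chain":
        n = max(spec.n_bodies, 2)
        m = spec.bars_per_edge or 5
        edges = [(i, i + 1, m) for i in range(n - 1)]
        truth = 6 + (n - 1) * (6 - m) if m >= 1 else None
        return Framework(bodies=list(range(n)), edges=edges, truth_dof=truth)
    if t == "coupled_hinges":
        # two hinged sub-pairs {0,1} and {2,3} (5-bar hinges) cross-linked
        # by a locked 0-2 edge and a single 1-3 bar: the two hinge angles
        # become mechanically shared, leaving one transmitted DOF between
        # the pairs (sites {0,1} vs {2,3} have A_max = B_max = AB_max = 7).
        edges = [(0, 1, 5), (2, 3, 5), (0, 2, 6), (1, 3, 1)]
        return Framework(bodies=[0, 1, 2, 3], edges=edges, truth_dof=7)
    if t == "two_blocks_bridged":
        # blocks {0,1,2} and {3,4,5}, each internally rigid (two 6-bar
        # links), joined by a single bar: 6 trivial + 5 relative DOF.
        edges = [
            (0, 1, 6),
            (1, 2, 6),
            (3, 4, 6),
            (4, 5, 6),
            (2, 3, 1),
        ]
        return Framework(bodies=list(range(6)), edges=edges, truth_dof=11)
    # random
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bodies
    bodies = list(range(n))
    edges: List[Edge] = []
    # connect with a random spanning tree, then sprinkle extra edges
    order = rng.permutation(n)
    for i in range(1, n):
        u = int(order[i])
        v = int(order[int(rng.integers(0, i))])
        edges.append((min(u, v), max(u, v), int(rng.integers(1, 7))))
    n_extra = int(rng.integers(0, max(1, n)))
    for _ in range(n_extra):
        u, v = rng.choice(n, size=2, replace=False)
        u, v = int(min(u, v)), int(max(u, v))
        edges.append((u, v, int(rng.integers(1, 7))))
    return Framework(bodies=bodies, edges=edges, truth_dof=None)


# ---------------------------------------------------------------------------
# Toy receptor
# ---------------------------------------------------------------------------

# Designed fold: a short "extracellular" arm Q (residues 1-4, acidic GLU 3),
# a central helix (5-13, CYS 6/9 disulfide, i->i+4 hydrogen-bond ladder) and
# a second arm P (14-18, acidic ASP 16) folded back so the two carboxylates
# face each other across ~4-5 Å.  The two arms are flexibly attached to the
# helix core; sink residues sit at the tip of arm Q and the scan range runs
# over arm P, so degrees of freedom transmit between them only when the
# acidic pair is bridged.  The ten inter-side-chain dihedrals and five chi
# angles below were tuned once, deterministically, to satisfy the contact
# and clash criteria.
_ARM_DIHEDRALS = {
    "psi3": 71.3, "phi4": -76.0, "psi4": -97.1, "phi5": -86.6,
    "psi13": -78.7, "phi14": -158.1, "psi14": -154.4, "phi15": 48.7,
    "psi15": -108.7, "phi16": -34.4,
}
_CHI_GLU3 = (-159.7, 145.7, 76.9)
_CHI_ASP16 = (144.7, 38.1)
_SS_BOND = 2.05  # Å, S-S
_CB_SG = 1.81  # Å


@dataclass(frozen=True)
class ToyReceptorParams:
    """Parameters of the toy protonated receptor.

    The defaults are the designed study fixture; switches exist to disable
    individual structural features for negative controls.
    """

    helix_len: int = 9
    hbond_ladder: bool = True
    disulfide: bool = True
    bridge_residues: Tuple[int, int] = (3, 16)
    sink_residues: Tuple[int, int, int] = (1, 2, 3)
    scan_range: Tuple[int, int] = (14, 18)
    psi_jitter_deg: float = 2.0
    seed: int = 7


@dataclass
class ToyReceptor:
    """Generated structure plus its manifest."""

    pdb_text: str
    n_atoms: int
    params: ToyReceptorParams
    bridge_atoms: Tuple[Tuple[int, str], Tuple[int, str]]  # (resnum, atom name)
    sink_residues: Tuple[int, ...]
    scan_range: Tuple[int, int]


def gen_toy_receptor(
    params: Optional[ToyReceptorParams] = None, seed: Optional[int] = None
) -> ToyReceptor:
    """Build the toy receptor; identical params + seed give identical text.

    Raises if the requested variant embeds with a steric clash (< 1.5 Å
    non-bonded contact).
    """
    from . import _peptide as pep

    p = params or ToyReceptorParams()
    if seed is not None:
        p = replace_dataclass(p, seed=seed)
    if p.helix_len != 9:
        raise ValueError(
            "helix_len is fixed at 9 in this design (arm geometry was tuned "
            "against it); build a new variant to change it"
        )
    rng = np.random.default_rng(p.seed)
    rs = pep.ResidueSpec
    A = _ARM_DIHEDRALS
    if p.hbond_ladder:
        helix_phi, helix_psi = -57.0, -47.0
    else:
        helix_phi, helix_psi = -139.0, 135.0
    jit = rng.uniform(-p.psi_jitter_deg, p.psi_jitter_deg, p.helix_len)

    res = [
        rs("GLY", -139, 135),
        rs("GLY", -139, 135),
        rs("GLU", -139, A["psi3"], _CHI_GLU3),
        rs("GLY", A["phi4"], A["psi4"]),
    ]
    helix_names = ["GLY"] * p.helix_len
    if p.disulfide:
        helix_names[1] = "CYS"
        helix_names[4] = "CYS"
    for k, nm in enumerate(helix_names):
        phi = A["phi5"] if k == 0 else helix_phi
        psi = A["psi13"] if k == p.helix_len - 1 else helix_psi + float(jit[k])
        res.append(rs(nm, phi, psi, (-60.0,) if nm == "CYS" else ()))
    res.append(rs("GLY", A["phi14"], A["psi14"]))
    res.append(rs("GLY", A["phi15"], A["psi15"]))
    res.append(rs("ASP", A["phi16"], 135, _CHI_ASP16))
    res.append(rs("GLY", -139, 135))
    res.append(rs("GLY", -139, 135))

    atoms = pep.build_chain(res)

    if p.disulfide:
        _reposition_disulfide(atoms, 6, 9)

    clash = pep.min_nonbonded_distance(atoms)
    if clash < 1.5:
        raise ValueError(
            f"parameter combination cannot be embedded without steric clash "
            f"(closest non-bonded contact {clash:.2f} Å)"
        )

    # name the bridging oxygens: closest carboxylate O pair
    pos = {(a.resnum, a.name): a.pos for a in atoms}
    r1, r2 = p.bridge_residues
    glu_os = [n for (r, n) in pos if r == r1 and n.startswith("OE")]
    asp_os = [n for (r, n) in pos if r == r2 and n.startswith("OD")]
    best = min(
        ((np.linalg.norm(pos[(r1, o1)] - pos[(r2, o2)]), o1, o2)
         for o1 in glu_os for o2 in asp_os),
        key=lambda t: t[0],
    )
    return ToyReceptor(
        pdb_text=pep.to_pdb(atoms),
        n_atoms=len(atoms),
        params=p,
        bridge_atoms=((r1, best[1]), (r2, best[2])),
        sink_residues=p.sink_residues,
        scan_range=p.scan_range,
    )


def replace_dataclass(obj, **kw):
    from dataclasses import replace

    return replace(obj, **kw)


def _reposition_disulfide(atoms, res_a: int, res_b: int) -> None:
    """Place the two SG atoms symmetrically on the CB-CB chord so that
    S-S = 2.05 Å and CB-SG = 1.81 Å exactly."""
    idx = {(a.resnum, a.name): i for i, a in enumerate(atoms)}
    cb_a = atoms[idx[(res_a, "CB")]].pos
    cb_b = atoms[idx[(res_b, "CB")]].pos
    d = float(np.linalg.norm(cb_b - cb_a))
    t = (d - _SS_BOND) / 2.0
    if not 0 < t < 2.1:
        raise ValueError(f"CB-CB distance {d:.2f} Å cannot host a disulfide")
    # stretch the C-S bond slightly if the chord is long (stays well inside
    # the covalent detection cutoff of 2.26 Å)
    cb_sg = max(_CB_SG, t + 0.1)
    h = math.sqrt(cb_sg**2 - t**2)
    u = (cb_b - cb_a) / d
    helix_cas = [a.pos for a in atoms if a.name == "CA" and 5 <= a.resnum <= 13]
    center = np.mean(helix_cas, axis=0)
    w0 = 0.5 * (cb_a + cb_b) - center
    w0 = w0 - np.dot(w0, u) * u
    nw = np.linalg.norm(w0)
    if nw < 1e-9:
        w0 = np.cross(u, np.array([0.0, 0.0, 1.0]))
        nw = np.linalg.norm(w0)
    w = w0 / nw
    atoms[idx[(res_a, "SG")]].pos = cb_a + t * u + h * w
    atoms[idx[(res_b, "SG")]].pos = cb_b - t * u + h * w


# ---------------------------------------------------------------------------
# Synthetic curves
# ---------------------------------------------------------------------------

CURVE_MODELS = (
    "lorentzian_mix",
    "linewidth_isotherm",
    "cpmg_dispersion",
    "saturation",
    "dose_response",
    "competition_two_site",
)


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one synthetic data table.

    `truth` holds the generating parameters of the chosen forward model (the
    models themselves live in :mod:`cation_allostery.nmr` and
    :mod:`cation_allostery.binding`); `design` the sampling points; `noise`
    the relative (multiplicative Gaussian) noise fraction.
    """

    model: str
    truth: dict
    design: dict
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in CURVE_MODELS:
            raise ValueError(f"unknown curve model {self.model!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _apply_noise(y: np.ndarray, noise: float, rng) -> np.ndarray:
    if noise == 0:
        return y
    return y * (1.0 + noise * rng.standard_normal(y.shape))


def gen_curve(spec: SyntheticCurveSpec) -> pd.DataFrame:
    """Generate one data table from the requested forward model.

    Column conventions (all plain CSV-ready):

    * lorentzian_mix:    freq_hz, intensity
    * linewidth_isotherm: conc_mM, linewidth_Hz
    * cpmg_dispersion:   field_MHz, nu_cpmg_Hz, R2eff_s1
    * saturation:        conc_nM, bound
    * dose_response:     conc_uM, response
    * competition_two_site: conc_nM, bound
    """
    rng = np.random.default_rng(spec.seed)
    t, d = dict(spec.truth), dict(spec.design)
    m = spec.model

    if m == "lorentzian_mix":
        freq = np.asarray(d["freq_hz"], dtype=float)
        components = t["components"]  # list of (center, fwhm, area)
        y = np.zeros_like(freq)
        for center, fwhm, area in components:
            if fwhm <= 0 or area < 0:
                raise ValueError("Lorentzian components need fwhm > 0, area >= 0")
            y += nmr.lorentzian(freq, center, fwhm, area)
        y = y + float(t.get("baseline", 0.0))
        y = _apply_noise(y, spec.noise, rng)
        return pd.DataFrame({"freq_hz": freq, "intensity": y})

    if m == "linewidth_isotherm":
        x = np.asarray(d["conc_mM"], dtype=float)
        if np.any(x <= 0):
            raise ValueError("concentrations must be strictly positive")
        kd, amp = float(t["kd_mM"]), float(t["amplitude"])
        if kd <= 0:
            raise ValueError("K_d must be positive")
        y = nmr.hyperbola(x, amp, kd)
        y = _apply_noise(y, spec.noise, rng)
        return pd.DataFrame({"conc_mM": x, "linewidth_Hz": y})

    if m == "cpmg_dispersion":
        model = nmr.DispersionModel(
            p_b=float(t["p_b"]),
            tau_b=float(t["tau_b_s"]),
            dw_ref=float(t["dw_ref_rad_s"]),
            ref_field=float(t.get("ref_field_MHz", d["fields_MHz"][0])),
            r2_0={float(f): float(r) for f, r in t["r2_0_s1"].items()}
            if isinstance(t["r2_0_s1"], dict)
            else {float(f): float(t["r2_0_s1"]) for f in d["fields_MHz"]},
        )
        nu = np.asarray(d["nu_cpmg_Hz"], dtype=float)
        if np.any(nu <= 0):
            raise ValueError("nu_CPMG values must be strictly positive")
        rows = []
        for fld in d["fields_MHz"]:
            y = nmr.cpmg_forward(model, nu, float(fld))
            y = _apply_noise(y, spec.noise, rng)
            for v, r in zip(nu, y):
                rows.append((float(fld), float(v), float(r)))
        return pd.DataFrame(rows, columns=["field_MHz", "nu_cpmg_Hz", "R2eff_s1"])

    if m == "saturation":
        L = np.asarray(d["conc_nM"], dtype=float)
        if np.any(L <= 0):
            raise ValueError("radioligand concentrations must be positive")
        y = binding.saturation_forward(
            L, float(t["bmax"]), float(t["kd_nM"]), float(t.get("ns", 0.0))
        )
        y = _apply_noise(y, spec.noise, rng)
        return pd.DataFrame({"conc_nM": L, "bound": y})

    if m == "dose_response":
        c = np.asarray(d["conc_uM"], dtype=float)
        if np.any(c <= 0):
            raise ValueError("cation concentrations must be positive")
        y = binding.dose_response_forward(
            c, float(t["e0"]), float(t["emax"]), float(t["ec50_uM"])
        )
        y = _apply_noise(y, spec.noise, rng)
        return pd.DataFrame({"conc_uM": c, "response": y})

    if m == "competition_two_site":
        I = np.asarray(d["conc_nM"], dtype=float)
        if np.any(I < 0):
            raise ValueError("competitor concentrations must be >= 0")
        L_star = float(t.get("radioligand_nM", 2.0))
        kd_star = float(t.get("radioligand_kd_nM", 1.0))
        ic50_high = binding.ki_to_ic50(float(t["k_high_nM"]), L_star, kd_star)
        ic50_low = binding.ki_to_ic50(float(t["k_low_nM"]), L_star, kd_star)
        y = binding.competition_forward(
            I,
            float(t["b0"]),
            float(t["f_high"]),
            ic50_high,
            ic50_low,
            float(t.get("ns", 0.0)),
        )
        y = _apply_noise(y, spec.noise, rng)
        return pd.DataFrame({"conc_nM": I, "bound": y})

    raise AssertionError("unreachable")


def default_competition_design() -> np.ndarray:
    """12 log-spaced competitor concentrations, 0.1 nM - 100 uM."""
    return np.logspace(-1, 5, 12)


# ---------------------------------------------------------------------------
# Scripted ion trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonPath:
    """One scripted ion: pinned at `distance_nm` from residue `residue` for
    the frame indices in `frames` (None = all frames); parked 5 nm away
    otherwise."""

    residue: int
    distance_nm: float
    frames: Optional[Tuple[int, ...]] = None
    species: str = "NA"


def gen_ion_trajectory(
    n_frames: int,
    ions: Sequence[IonPath],
    n_residues: int = 12,
    seed: int = 0,
) -> str:
    """Multi-model PDB text: a static CA-only peptide plus scripted ions.

    Contact fractions are known exactly from the scripts: an ion listed with
    `frames` covering k of `n_frames` frames at distance d contributes k /
    n_frames at any cutoff > d and 0 at any cutoff < d (to its residue).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if not ions:
        raise ValueError("need at least one ion")
    # residue i at (7.0 * i, 0, 0) angstrom: 70 nm apart guarantees an ion
    # pinned near one residue is far outside any sensible cutoff of others
    res_pos = {i + 1: np.array([70.0 * i, 0.0, 0.0]) for i in range(n_residues)}
    lines: List[str] = []
    for frame in range(n_frames):
        lines.append(f"MODEL     {frame + 1:4d}")
        serial = 1
        for resi in range(1, n_residues + 1):
            x, y, z = res_pos[resi]
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY A{resi:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        for k, ion in enumerate(ions):
            if ion.residue not in res_pos:
                raise ValueError(f"ion references unknown residue {ion.residue}")
            active = ion.frames is None or frame in ion.frames
            base = res_pos[ion.residue]
            if active:
                pos = base + np.array([0.0, ion.distance_nm * 10.0, 0.0])
            else:
                pos = base + np.array([0.0, 50.0, 0.0])  # 5 nm: out of range
            name = ion.species.upper().rjust(2)
            lines.append(
                f"HETATM{serial:5d} {name:>3s}  {ion.species.upper():<3s} I{k + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          {ion.species.upper():>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
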