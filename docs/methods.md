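# Methods

## Constraint networks

A protonated structure is mapped onto a body-bar framework: every atom is a
rigid body with six degrees of freedom; interactions are multi-bar edges,
each bar removing one relative degree of freedom.

* **Covalent bonds** are detected from element-pair distance tables
  (covalent radii + 0.45 Å tolerance; hydrogens bond only to their nearest
  heavy atom). A rotatable bond carries 5 bars, leaving the torsion free.
  Bonds to atoms of covalent degree one (carbonyl oxygens, hydrogens) are
  locked at 6 bars: a 5-bar bond to a point-like atom would leave a
  physically meaningless "spin" degree of freedom that inflates site DOF
  counts. The peptide C–N bond is locked (6 bars); disulfides (S–S ≤ 2.5 Å)
  carry 5 bars.
* **Hydrogen bonds** pass a geometric screen (donor–acceptor ≤ 3.6 Å,
  H–acceptor ≤ 2.6 Å, donor angle ≥ 110°) and are ranked with a Mayo 12-10
  potential,

      E = V0·[5(d0/d)^12 − 6(d0/d)^10]·F(θ, φ),

  with V0 = 8 kcal/mol, d0 = 2.8 Å, d the donor–acceptor distance,
  θ the D–H···A angle and φ the H···A–base angle. The angular factor
  F = cos²θ·exp(−(π−θ)⁶)·cos²(φ−φ0) uses φ0 = 109.5° for sp³ acceptors and
  120° for sp² (hybridizations from a residue/atom-name table; unknown atoms
  default to sp³). Only attractive bonds (E < 0) enter the network, with 5
  bars. Charged donor/acceptor pairs are not treated separately from
  hydrogen bonds: a salt-bridge contact passing the screen enters with its
  Mayo energy. All cutoffs and bar counts are config-exposed
  (`NetworkParams`).
* **Hydrophobic tethers** (2 bars) connect apolar C/S atoms — atoms with no
  covalent N/O neighbour, which excludes backbone Cα and carbonyl carbons —
  of sequence-distant residues within the van der Waals sum + 0.25 Å.
* **Cation bridges** rigidify acidic pairs. `explicit_ion` adds the cation
  as a new body with locked (6-bar) edges to each coordinating atom;
  `direct_lock` adds a locked edge between the coordinating atoms. A
  chelated divalent ion is treated as rigidly coordinated, which makes the
  two realizations mechanically equivalent (identical cluster
  decompositions); bridge edges are never removed by the energy filter.

Filtering at cutoff `E_cut ≤ 0` retains hydrogen bonds with E ≤ E_cut, i.e.
at least that strong; the retained set is monotone in the cutoff.

## Pebble game and DOF counting

Generic rigidity of 3-D body-bar frameworks is characterized by the
(6,6)-sparsity matroid, decided by the (6,6) pebble game: each body holds 6
pebbles and a bar is inserted only if 7 pebbles can be gathered on its two
endpoints; an edge of multiplicity m is processed as m independent bars.
Searches are depth-first with ascending body order, making cluster labels
and counts reproducible bit-for-bit.

The degrees of freedom of an arbitrary site (atom set) are counted by
maximal pebble collection on the site after all bars are inserted,
retrieving pebbles from outside the site only. This count equals the
dimension of the projection of the framework's infinitesimal-motion space
onto the site's coordinates. Rigid clusters are computed by union-find over
adjacent co-rigid pairs (a pair is co-rigid when at most 6 pebbles can be
gathered on it); in the (6,6) matroid rigid components are vertex-disjoint
connected subgraphs, so adjacent pairs suffice.

Correctness is anchored to an independent oracle: a generic rigidity matrix
with random bar endpoints (three seeded realizations, majority value) whose
null-space projection rank gives the same site DOF. The test suite requires
exact agreement — site DOF, co-rigidity and transmitted DOF — on hundreds
of random frameworks.

## Rigidity-transmission allostery

For disjoint sites A and B, DOF_AB = A_max + B_max − AB_max − 6, the six
removing the shared trivial rigid-body motions. Positive DOF_AB means some
non-trivial motion of A is mechanically locked to a motion of B. Negative
raw values (independent flexibility) are reported but clamped to zero in
curves and intensities, since only positive transmission is interpreted.
Note that a site's projected DOF is at most 6 per body it contains, so
transmission requires *internally flexible* sites whose internal motions
are correlated — a single atom or an internally rigid cluster can never
transmit.

A transmission curve sweeps the hydrogen-bond cutoff from 0 to −6 kcal/mol
in 0.01 kcal/mol steps (endpoints config-exposed; only the increment is
prescribed). The curve is piecewise constant between the discrete bond
energies, so the engine evaluates one pebble game per distinct retained-bond
set and fills the grid from a cache. Intensity is the rectangle-rule area
under the clamped curve — appropriate because the integrand is piecewise
constant and integer-valued.

Window scans perturb three consecutive residues (r, r+1, r+2), all atoms
including side chains (side-chain hydrogen bonds carry the loop
constraints; a backbone-only site can be selected by passing the
corresponding atom subset). A residue's intensity is the mean over the (up
to three) windows containing it; terminal residues of the range use the
windows that exist.

## The toy receptor

The structure fixture is an idealized 18-residue peptide built from
internal coordinates (canonical bond lengths/angles, chosen φ/ψ/χ, trans
peptides) rather than energy minimization — sufficient for constraint
detection and fully deterministic. Its fold: a 4-residue arm Q carrying the
sink residues (1–3) and an acidic glutamate (3); a 9-residue α-helix
(i→i+4 hydrogen-bond ladder, energies graded −1.2 to −3.8 kcal/mol by a
seeded ±2° ψ jitter; CYS 6/9 disulfide placed exactly at S–S 2.05 Å); and a
5-residue arm P (the scan range, 14–18) carrying an aspartate (16) whose
carboxylate faces the glutamate's across 4.2 Å. The ten inter-side-chain
dihedrals and five χ angles were tuned once, deterministically, to satisfy
the contact and clash (≥ 1.5 Å non-bonded) criteria.

Mechanically, the two arms hang flexibly from the rigid helix core, so no
window on arm P transmits any DOF to the sink on arm Q — every unbridged
per-residue intensity is exactly zero. Rigidifying the acidic pair with a
cation bridge closes a ring through both arms: windows covering residues
14–16 then transmit 1–2 DOF over a band of cutoffs, and no window's
intensity decreases. This is the designed qualitative analogue of
extracellular divalent-cation bridges propagating rigidity to the
G-protein-binding cleft.

## NMR models

**Deconvolution.** Spectra are fitted as sums of area-parameterized
Lorentzians plus a flat baseline by least squares; populations are area
fractions, so they are direct fit outputs and sum to one by construction.
Initialization picks the k strongest separated local maxima; a
deterministic multi-start (width scales ×0.5/1/2 plus seeded center
jitters) takes the best residual. Optional per-component bounds on centers
and widths implement the practice of constraining linewidths from
independent T₂ measurements — without them, heavily overlapped components
can collapse into spurious optima, which the fitter flags as `degenerate`
instead of returning silently. Raw-FID processing (apodization,
zero-filling) is out of scope; the fixture generator emulates apodization
only as extra Lorentzian width.

**Isotherms.** Fast-exchange titrations are fitted to y = A·x/(K_d + x);
displacement series to y = y_inf + (y0 − y_inf)·K_i/(K_i + x). Confidence
intervals come from the fit covariance.

**CPMG.** The two-site fast-exchange (Luz–Meiboom) profile

    R2eff(ν) = R2,0 + (Φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)],
    Φ = p_b(1−p_b)·Δω²,  k_ex = k_off/(1−p_b),  τ_b = 1/k_off

is chosen because the ²³Na resonance is a single population-averaged line
in the fast-exchange regime; Carver–Richards and spin-3/2 multi-exponential
relaxation are out of scope. In this limit only (Φ, k_ex) are identifiable
— Φ scales exactly as field², so a second field constrains the model but
cannot separate p_b from Δω. The global fitter therefore fits shared
(Φ_ref, k_ex) and per-field R2,0 across fields (deterministic multi-start
over k_ex), takes Δω as a known constant (from the shift titration), and
converts to (p_b, τ_b) via the dilute root of Φ = p(1−p)Δω². Flat data are
flagged "no exchange detected" (amplitude Φ/k_ex below 0.05 s⁻¹ by
default). The bound-fraction change between conditions is reported as a
relative change (the +20% reading), computed per paired seed.

**Study conditions.** Where the study prints values they are used directly:
K_d = 61 mM (apo sodium isotherm), τ_b = 480 μs (apo) and 630 μs (inverse
agonist), +20% bound fraction, and the competition table below. Unprinted
settings were fixed once at realistic values: two fields as the ²³Na Larmor
frequencies of 600/700-MHz instruments (158.7/185.2 MHz), 12 log-spaced
ν_CPMG points over 50–2000 Hz, p_b(apo) = 3×10⁻⁴ (≈50 μM receptor against
~10² mM Na⁺ at K_d 61 mM), R2,0 = 22/25 s⁻¹, and an effective Δω of
2×10⁴ rad/s chosen so the exchange contribution to R2 (Φ/k_ex ≈ 60 s⁻¹)
sits on the scale implied by the linewidth titration's ~150 Hz plateau — a
dispersion amplitude the experiment could actually measure. Noise is
multiplicative Gaussian (5% isotherms, 2% dispersions, 3% binding curves),
matching the relative-error character of NMR intensities and counting
statistics.

## Binding models

Saturation: B(L) = Bmax·L/(K_d+L) + ns·L. Dose–response:
E(c) = E0 + (Emax−E0)·c/(EC50+c), with decreasing responses permitted
(Zn²⁺-like). Competition:

    B(I) = B0·[f_high/(1+I/IC50_high) + (1−f_high)/(1+I/IC50_low)] + NS

with one- vs two-site selection by the extra-sum-of-squares F-test at
α = 0.05 and Cheng–Prusoff conversion of IC50s to affinities. K_high ≤
K_low is enforced by relabelling; a two-site fit whose both affinity CIs
span more than a decade is flagged unidentifiable. The recovery experiments
generate curves at the printed table rows (K_high 14.10/9.18/2.58 nM,
K_low 950/1060/708 nM, f_high 26.6/33.7/36.7%) on 12 log-spaced
concentrations (0.1 nM–100 μM) with 2 nM radioligand; the radioligand
affinity used for Cheng–Prusoff is fixed at 1 nM — the recovery targets
compare fitted to generating values, so this assumed constant cancels.

## Geometry metrics

Minimal inter-residue distances use heavy atoms by default (crystal
structures lack hydrogens; flag to include them). Ion contact fractions
count, per residue and cutoff (0.3/0.6 nm), the fraction of (frame, ion)
observations with the ion within the cutoff of any residue atom; the
alternative normalization (mean ions-in-contact per frame) is available
because the published histograms' normalization is not fully specified.
Trajectories are consumed as multi-model PDB to stay text-only; other
readers can be plugged in upstream.

## What the synthetic data do and do not show

The generators emulate the *forward models* of each analysis stage plus the
structural motifs the rigidity engine consumes. Passing tests demonstrate
that the estimators are unbiased and precise at realistic noise on data
drawn from their own models, and that the rigidity/transmission machinery
is exactly correct on frameworks where ground truth is computable. They do
not validate the models against real receptor data: real ¹⁹F spectra carry
baseline and phase artifacts, ²³Na relaxation is multi-exponential
(spin 3/2), membranes deplete ligand, and the published RTA maps were run
on MD-derived conformers of the actual receptor, none of which are
reproducible from printed information. Numerical tolerances in the tests
are correspondingly tiered: exact for combinatorics and scripted geometry,
optimizer-tolerance for noiseless fits, and 5–25% bands for medians of
noisy-replicate recoveries.

## Problem sizes

Default runs use the sizes stated above — 200-framework oracle comparisons
(≤ 12 bodies), a 103-atom structure fixture, 601-point cutoff sweeps, and
25–60 replicate recoveries — which keep the full suite and the acceptance
script to a few minutes on one CPU while leaving every estimate's
Monte-Carlo error well inside its acceptance band.
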