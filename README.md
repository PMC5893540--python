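# cation-allostery

Analysis pipeline for studying how physiological cations allosterically
modulate a class A GPCR (the A₂A adenosine receptor), combining combinatorial
rigidity theory with quantitative NMR and radioligand binding analysis. The
package re-implements, as tested library code exercisable on synthetic data
with known ground truth:

* a **(6,6) pebble-game rigidity engine** for body-bar constraint networks
  built from protonated structures (covalent bonds, Mayo-ranked hydrogen
  bonds, disulfides, hydrophobic tethers, cation bridges), verified against
  an independent dense rigidity-matrix oracle;
* **rigidity-transmission allostery (RTA)** scanning: for a perturbation
  window A and the G-protein-binding sink B (residues 208/230/291 at the
  intracellular tips of TM5–7), the transmitted degrees of freedom

      DOF_AB = A_max + B_max − AB_max − 6,

  swept over the hydrogen-bond energy cutoff in 0.01 kcal/mol steps and
  integrated into a per-residue transmission intensity;
* **NMR quantitation**: multi-Lorentzian deconvolution of ¹⁹F spectra into
  the S₁₋₂ / S₃ / S₃′ state populations, hyperbolic fast-exchange isotherms
  *y = A·x/(K_d + x)* for ²³Na/²⁵Mg titrations, and global two-field
  Luz–Meiboom CPMG fits for the ion bound fraction and bound-state lifetime
  τ_b = 1/k_off;
* **radioligand models**: one-site saturation, cation dose–response, and
  one- vs two-site competition (extra-sum-of-squares F-test, Cheng–Prusoff
  conversion K_i = IC50/(1 + [L*]/K_d*));
* **geometry metrics**: minimal inter-residue distances and per-residue ion
  contact fractions at 0.3/0.6 nm cutoffs over multi-model series.

Everything runs on deterministic synthetic fixtures generated by the
package itself — body-bar frameworks with oracle-known DOF, a designed toy
protonated receptor (hydrogen-bond ladder, disulfide, acidic bridge pair,
sink residues), spectra, isotherms, dispersions and binding curves.

## Layout

    src/cation_allostery/   library (fixtures, structure_io, pebble, rta,
                            nmr, binding, metrics, study, cli)
    analysis/               numbered drivers, one per analysis stage
    results/                tables written by the drivers
    scripts/acceptance.py   end-to-end recomputation of the headline numbers
    tests/                  pytest suite

A `cation-allostery` console entry point exposes the individual steps
(`decompose`, `rta-scan`, `deconvolve`, `fit-isotherm`, `fit-cpmg`,
`fit-competition`, `contacts`, `distances`).

## Worked example

Rigidity transmission from the toy receptor's extracellular arm to the
G-protein-site sink, with and without the divalent-cation bridge between
its two acidic side chains:

```bash
$ python analysis/03_bridge_transmission_scan.py
 residue  intensity_unbridged  intensity_bridged    delta
      14                  0.0           2.480000 2.480000
      15                  0.0           1.240000 1.240000
      16                  0.0           0.826667 0.826667
      17                  0.0           0.000000 0.000000
      18                  0.0           0.000000 0.000000

bridging the 3-16 acidic pair raises transmission at 3/5 scanned residues and lowers none (min delta 0.000)
```

Without the bridge no window transmits any degrees of freedom to the sink
(the two arms move independently); rigidifying the acidic pair couples
their motions and windows covering residues 14–16 transmit 1–2 DOF over a
~1–2.5 kcal/mol-wide band of hydrogen-bond cutoffs — the area under that
band is the printed intensity. This is the qualitative mechanism by which
extracellular divalent-cation bridges propagate rigidity to the
G-protein-binding cleft.

The NMR stage of the same pipeline:

```bash
$ python analysis/05_cpmg_lifetimes.py
apo lifetime: median 478 us (truth 480)
inverse-agonist lifetime: median 632 us (truth 630)
bound-fraction change: median +20.5% (truth +20%) over 25 paired seeds
```

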