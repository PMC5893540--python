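#!/usr/bin/env python
"""Window-scan rigidity transmission with and without the cation bridge.

Slides the three-residue perturbation window over the toy receptor's
"extracellular" arm and measures the DOF transmitted to the sink residues,
sweeping the hydrogen-bond cutoff in 0.01 kcal/mol steps, before and after
rigidifying the acidic-pair cation bridge.  Writes per-residue intensities
and deltas to results/.
"""

import os

import pandas as pd

from cation_allostery import fixtures, rta, structure_io as sio

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    toy = fixtures.gen_toy_receptor()
    st = sio.read_structure(toy.pdb_text)
    net = sio.build_network(st)
    ai = {(a.resnum, a.name): i for i, a in enumerate(net.atoms)}
    (r1, o1), (r2, o2) = toy.bridge_atoms
    bridge = rta.BridgeSpec(atoms=(ai[(r1, o1)], ai[(r2, o2)]),
                            mode="explicit_ion", label=f"{r1}-{r2}")

    cmp = rta.bridge_comparison(net, [bridge], toy.scan_range,
                                toy.sink_residues, sweep=(0.0, -6.0, 0.01))
    df = pd.DataFrame({
        "residue": list(cmp.base.residue_intensity),
        "intensity_unbridged": list(cmp.base.residue_intensity.values()),
        "intensity_bridged": list(cmp.bridged.residue_intensity.values()),
        "delta": list(cmp.delta.values()),
    })
    os.makedirs(OUT, exist_ok=True)
    df.to_csv(os.path.join(OUT, "bridge_transmission.csv"), index=False)
    print(df.to_string(index=False))
    raised = (df["delta"] > 0).sum()
    print(f"\nbridging the {r1}-{r2} acidic pair raises transmission at "
          f"{raised}/{len(df)} scanned residues and lowers none "
          f"(min delta {df['delta'].min():.3f})")


if __name__ == "__main__":
    main()
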