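#!/usr/bin/env python
"""Sodium linewidth-isotherm K_d recovery at the apo ground truth.

Generates 60 noisy synthetic ²³Na titrations (K_d 61 mM, 5% multiplicative
noise) and fits each with the hyperbolic fast-exchange model, writing the
per-replicate fits to results/.
"""

import os

from cation_allostery import study

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    df = study.isotherm_recovery(seed=1)
    os.makedirs(OUT, exist_ok=True)
    df.to_csv(os.path.join(OUT, "isotherm_recovery.csv"), index=False)
    med = df["kd_mM"].median()
    q1, q3 = df["kd_mM"].quantile([0.25, 0.75])
    print(f"median fitted K_d {med:.1f} mM (IQR {q1:.1f}-{q3:.1f}) over "
          f"{len(df)} replicates; generating value {study.NA_ISOTHERM_KD_MM} mM")


if __name__ == "__main__":
    main()
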