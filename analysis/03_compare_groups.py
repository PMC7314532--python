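#!/usr/bin/env python
"""Group comparison: two-way (group x cortical layer) ANOVA with pooling.

Reads the fitted per-depth table, forms animal x layer cell means over
layers III-VI, runs the two-way ANOVA per parameter, applies the pooling
rule (pool layers when neither the layer effect nor the interaction is
significant) and reports the pooled group contrast.
"""

import json
from pathlib import Path

import pandas as pd

from ecsdiff.rti import compare_groups

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "cohort_fits.csv")
    res = compare_groups(table)

    out = {}
    for param in ("alpha", "lam"):
        aov = res.anova[param]
        out[param] = {
            "anova": {
                factor: {
                    "F": float(aov.loc[factor, "F"]),
                    "df": float(aov.loc[factor, "df"]),
                    "p": float(aov.loc[factor, "PR(>F)"]),
                }
                for factor in ("group", "layer", "group:layer")
            },
            "layers_pooled": res.pooled_applied[param],
            "pooled_contrast": res.pooled[param],
        }
        g = aov.loc["group"]
        print(
            f"{param}: group F({g['df']:.0f},{aov.loc['Residual', 'df']:.0f}) "
            f"= {g['F']:.2f}, p = {g['PR(>F)']:.2g}; "
            f"layer p = {aov.loc['layer', 'PR(>F)']:.2f}; "
            f"pooled = {res.pooled_applied[param]}"
        )
    (RESULTS / "anova.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {RESULTS / 'anova.json'}")


if __name__ == "__main__":
    main()
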