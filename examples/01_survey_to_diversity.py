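"""From a plot survey to per-compartment Shannon diversity.

Builds a tiny two-plot relevé table with Braun-Blanquet codes, pools the
covers per compartment and computes the Shannon-Wiener index H'.
"""

import pandas as pd

from urbes import diversity_table, pool_covers

surveys = pd.DataFrame(
    {
        "plot_id": ["p1", "p1", "p1", "p2", "p2"],
        "compartment_id": ["MF"] * 5,
        "species": ["quercus ilex", "hedera helix", "ruscus aculeatus",
                    "quercus ilex", "hedera helix"],
        "bb": ["3", "1", "+", "5", "2"],
    }
)

pooled = pool_covers(surveys, "MF")
print("pooled mean cover fractions (absence in a plot counts as 0):")
print(pooled.to_string(), "\n")

table = diversity_table(surveys, ["MF"])
print(table.to_string(index=False))
print(
    "\nrichness is the number of species pooled over the compartment's plots;\n"
    "shannon is H' = -sum p ln p over the pooled relative covers (max ln 3 = 1.10)."
)
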