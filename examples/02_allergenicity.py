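"""Pollen-allergenicity disservice for one landscape compartment.

Evaluates the modified Index of Urban Green Zones Allergenicity
(modI_UGZA) for a two-species community on a 1 ha compartment and
classifies it against the 0.3 pollen-risk threshold.
"""

import pandas as pd

from urbes import Compartment, mod_iugza

compartment = Compartment("MF", "forest", "managed", area_ha=1.0)
traits = pd.DataFrame(
    {
        "species": ["quercus ilex", "festuca rubra"],
        "vpa": [0.8, 0.3],          # potential allergenic value, dimensionless in [0, 1]
        "height_m": [20.0, 1.0],    # mean mature height
    }
).set_index("species")
pooled_covers = {"quercus ilex": 0.375, "festuca rubra": 0.175}

result = mod_iugza(pooled_covers, traits, compartment)
print(f"modI_UGZA = {result.index:.4f}  (threshold {result.threshold}, at_risk={result.at_risk})")
print(
    "\nthe index weights each species' occupied surface (cover x S_c) by its\n"
    "allergenic value and height, normalized by the compartment maxima, so it\n"
    "always lies in [0, 1]; 0.3783 >= 0.3 flags a pollen-allergy risk."
)
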