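"""Pollen-related disservice: the modified Index of Urban Green Zones
Allergenicity (modI_UGZA).

For a landscape compartment of surface S_c (m^2) holding k surveyed
species, each with potential allergenic value VPA_i in [0, 1], mean height
H_i (m) and Braun-Blanquet-estimated occupied surface SBB_i (m^2):

    modI_UGZA = sum_i( VPA_i * SBB_i * H_i ) / (maxH * maxVPA * S_c)

maxH and maxVPA are the maxima over the k species found in that
compartment.  SBB_i is operationalized as the pooled mean cover fraction
times S_c, which keeps the index in [0, 1] by construction (a single
species at full cover with the compartment maxima yields exactly 1).  An
index at or above 0.3 signals a risk of triggering pollen allergies in
sensitive individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .surveys import Compartment, ValidationError, pool_covers

__all__ = [
    "RISK_THRESHOLD",
    "AllergenicityResult",
    "mod_iugza",
    "classify_risk",
    "allergenicity_table",
]

logger = logging.getLogger(__name__)

#: Pollen allergy-risk threshold on modI_UGZA (index ranges over [0, 1]).
RISK_THRESHOLD: float = 0.3

# Floor for maxVPA in the degenerate all-VPA-zero community, to avoid 0/0
# while still returning an index of 0.
_VPA_FLOOR = 1e-9


@dataclass(frozen=True)
class AllergenicityResult:
    compartment_id: str
    index: float
    at_risk: bool
    threshold: float = RISK_THRESHOLD


def classify_risk(index: float, threshold: float = RISK_THRESHOLD) -> bool:
    """True iff the index reaches the allergy-risk threshold.

    The comparison is inclusive: an index exactly at the threshold counts
    as a risk equal to the limit.
    """
    if not 0.0 <= index <= 1.0:
        raise ValidationError(f"index must lie in [0, 1], got {index}")
    return index >= threshold


def mod_iugza(
    pooled_covers: Mapping[str, float] | pd.Series,
    traits: pd.DataFrame,
    compartment: Compartment,
    threshold: float = RISK_THRESHOLD,
) -> AllergenicityResult:
    """Evaluate modI_UGZA for one compartment.

    ``pooled_covers`` maps species name to mean cover fraction (as from
    :func:`urbes.surveys.pool_covers`); ``traits`` is indexed by species
    with columns ``vpa`` and ``height_m``.  Every species with positive
    cover must have a trait row.
    """
    covers = pd.Series(pooled_covers, dtype=float)
    covers = covers[covers > 0]
    if covers.empty:
        return AllergenicityResult(compartment.id, 0.0, classify_risk(0.0, threshold), threshold)

    missing = sorted(set(covers.index) - set(traits.index))
    if missing:
        raise ValidationError(f"species missing from trait table: {missing}")

    sub = traits.loc[covers.index]
    s_c = compartment.area_m2
    if not s_c > 0:
        raise ValidationError(f"compartment {compartment.id!r}: S_c must be > 0")

    sbb = covers * s_c  # occupied surface per species, m^2
    max_h = float(sub["height_m"].max())
    max_vpa = float(sub["vpa"].max())
    if max_vpa <= 0:
        logger.warning(
            "compartment %s: all VPA are zero; index defined as 0", compartment.id
        )
        max_vpa = _VPA_FLOOR
    numerator = float((sub["vpa"] * sbb * sub["height_m"]).sum())
    index = numerator / (max_h * max_vpa * s_c)
    return AllergenicityResult(compartment.id, index, classify_risk(index, threshold), threshold)


def allergenicity_table(
    surveys: pd.DataFrame,
    traits: pd.DataFrame,
    compartments: Iterable[Compartment],
    threshold: float = RISK_THRESHOLD,
) -> pd.DataFrame:
    """modI_UGZA and risk class per compartment.

    Returns a DataFrame ``compartment_id, index, at_risk, threshold``.
    """
    rows = []
    for comp in compartments:
        pooled = pool_covers(surveys, comp)
        rows.append(mod_iugza(pooled, traits, comp, threshold).__dict__)
    return pd.DataFrame(rows)
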