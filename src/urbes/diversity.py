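"""Shannon-Wiener diversity from pooled Braun-Blanquet covers.

One H' per compartment: relative abundances p_i are the pooled mean cover
fractions renormalized to sum to one, and H' = -sum p_i ln p_i (natural
log).  H' is therefore invariant to rescaling all covers by a positive
constant, lies in [0, ln k] for k species, and attains ln k exactly when
all covers are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .surveys import Compartment, ValidationError, pool_covers

__all__ = ["DiversityResult", "shannon_index", "diversity_table", "write_diversity"]


@dataclass(frozen=True)
class DiversityResult:
    compartment_id: str
    richness: int
    shannon: float


def shannon_index(pooled_covers: Mapping[str, float] | pd.Series) -> float:
    """Shannon-Wiener H' = -sum p_i ln p_i from per-species covers.

    Species with zero cover are dropped (0 ln 0 := 0).  Raises if no
    species has positive cover.
    """
    cov = np.asarray(pd.Series(pooled_covers), dtype=float)
    if (cov < 0).any():
        raise ValidationError("covers must be non-negative")
    cov = cov[cov > 0]
    total = cov.sum()
    if cov.size == 0 or total <= 0:
        raise ValidationError("no vegetation: all covers are zero")
    p = cov / total
    return float(-(p * np.log(p)).sum())


def diversity_table(
    surveys: pd.DataFrame, compartments: Iterable[Compartment | str]
) -> pd.DataFrame:
    """Richness and H' per compartment, from pooled covers.

    Returns a DataFrame with columns ``compartment_id, richness, shannon``.
    """
    rows = []
    for comp in compartments:
        cid = comp.id if isinstance(comp, Compartment) else comp
        pooled = pool_covers(surveys, cid)
        pooled = pooled[pooled > 0]
        rows.append(
            DiversityResult(
                compartment_id=cid,
                richness=int(pooled.size),
                shannon=shannon_index(pooled),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def write_diversity(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
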