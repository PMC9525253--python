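"""ES-ED trade-off scoring.

Raw per-compartment indicator magnitudes (carbon storage, avoided runoff,
Shannon H', allergenicity index, ...) are standardized per indicator by the
highest value reached in the study area, giving scores in [0, 1] where 1
marks the best-provisioning compartment.  Disservice (ED) scores are then
negated into [-1, 0].  Compartments for which an indicator cannot be
assessed score 0 for that indicator and still enter the denominator of the
per-compartment arithmetic mean over all N indicators — the "averaged
ES-ED score" in [-1, 1] that the trade-off maps display.

Each indicator is assumed equally important; an optional weight vector can
replace the uniform default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .surveys import ValidationError

__all__ = [
    "Indicator",
    "RBC_INDICATORS",
    "standardize",
    "averaged_es_ed",
    "per_hectare",
    "total_from_per_hectare",
]


@dataclass(frozen=True)
class Indicator:
    """One assessed service (ES) or disservice (ED)."""

    id: str
    label: str
    units: str
    orientation: str  # "ES" | "ED"

    def __post_init__(self) -> None:
        if self.orientation not in ("ES", "ED"):
            raise ValidationError(
                f"indicator {self.id!r}: orientation must be 'ES' or 'ED'"
            )


#: The ten indicators of the reference study area (8 ES + 2 ED).  The set
#: is configurable: any list of :class:`Indicator` may be passed instead.
RBC_INDICATORS: tuple[Indicator, ...] = (
    Indicator("shannon", "Shannon index", "-", "ES"),
    Indicator("carbon_storage", "Carbon storage", "Mg ha-1", "ES"),
    Indicator("gross_sequestration", "Gross carbon sequestration", "kg ha-1 y-1", "ES"),
    Indicator("net_sequestration", "Net carbon sequestration", "kg ha-1 y-1", "ES"),
    Indicator("avoided_runoff", "Avoided runoff", "m3 y-1", "ES"),
    Indicator("oxygen_production", "Oxygen production density", "kg y-1 ha-1", "ES"),
    Indicator("pollution_removal", "Pollution removal", "kg y-1", "ES"),
    Indicator("uv_reduction", "UV effects reduction", "%", "ES"),
    Indicator("voc_emission", "VOCs emission", "kg y-1", "ED"),
    Indicator("allergenicity", "Allergenicity index", "-", "ED"),
)


def standardize(
    raw: pd.DataFrame,
    indicators: Iterable[Indicator] = RBC_INDICATORS,
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Standardize raw values into the signed score matrix.

    ``raw`` is the long table read by :func:`urbes.surveys.read_raw_values`
    (``indicator_id, compartment_id, value, orientation, assessable``).
    Each assessable cell is divided by its indicator's maximum over the
    compartments (ties all score 1), ED columns are negated, and
    non-assessable or unreported cells are 0.

    ``overrides`` maps ``(indicator_id, compartment_id)`` to an
    already-signed score, for cells whose score is known but whose raw
    magnitude is not; they are applied after standardization.

    Returns a DataFrame with compartments as rows (sorted by the order of
    first appearance in ``raw``) and one column per indicator.
    """
    indicators = list(indicators)
    if not indicators:
        raise ValidationError("empty indicator set")
    orient = {ind.id: ind.orientation for ind in indicators}
    unknown = sorted(set(raw["indicator_id"]) - set(orient))
    if unknown:
        raise ValidationError(f"raw values for undeclared indicator(s): {unknown}")
    mismatch = raw[raw["orientation"] != raw["indicator_id"].map(orient)]
    if not mismatch.empty:
        raise ValidationError(
            f"orientation mismatch for indicator(s): {sorted(set(mismatch['indicator_id']))}"
        )

    comp_ids = list(dict.fromkeys(raw["compartment_id"]))
    overrides = dict(overrides or {})
    scores = pd.DataFrame(0.0, index=pd.Index(comp_ids, name="compartment_id"),
                          columns=[ind.id for ind in indicators])

    for ind in indicators:
        sub = raw[(raw["indicator_id"] == ind.id) & raw["assessable"]]
        overridden = {c for (i, c) in overrides if i == ind.id}
        if sub.empty:
            if not overridden:
                raise ValidationError(
                    f"indicator {ind.id!r} has no assessable values and no overrides"
                )
        else:
            vmax = float(sub["value"].max())
            if not vmax > 0:
                raise ValidationError(f"indicator {ind.id!r} has no positive maximum")
            col = sub.set_index("compartment_id")["value"] / vmax
            if ind.orientation == "ED":
                col = -col
            scores.loc[col.index, ind.id] = col

    for (ind_id, comp_id), value in overrides.items():
        if ind_id not in scores.columns:
            raise ValidationError(f"override for undeclared indicator {ind_id!r}")
        if comp_id not in scores.index:
            raise ValidationError(f"override for unknown compartment {comp_id!r}")
        scores.at[comp_id, ind_id] = float(value)

    return scores


def averaged_es_ed(
    scores: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> pd.Series:
    """Per-compartment averaged ES-ED score.

    Arithmetic mean of each compartment's row over ALL indicator columns —
    signed ED scores and the zeros of non-assessed cells included — or a
    weighted mean when ``weights`` (indicator_id -> weight) is given.
    """
    if scores.shape[1] == 0:
        raise ValidationError("empty indicator set")
    if weights is None:
        out = scores.mean(axis=1)
    else:
        w = pd.Series(weights, dtype=float).reindex(scores.columns)
        if w.isna().any():
            raise ValidationError(
                f"missing weight for indicator(s): {sorted(scores.columns[w.isna()])}"
            )
        if not w.sum() > 0:
            raise ValidationError("weights must have a positive sum")
        out = scores.mul(w, axis=1).sum(axis=1) / w.sum()
    out.name = "averaged_es_ed"
    return out


def per_hectare(total: float, area_ha: float) -> float:
    """Convert a compartment total to a per-hectare density."""
    if not area_ha > 0:
        raise ValidationError(f"area_ha must be > 0, got {area_ha}")
    return total / area_ha


def total_from_per_hectare(per_ha: float, area_ha: float) -> float:
    """Convert a per-hectare density back to a compartment total."""
    if not area_ha > 0:
        raise ValidationError(f"area_ha must be > 0, got {area_ha}")
    return per_ha * area_ha


def scores_long(scores: pd.DataFrame) -> pd.DataFrame:
    """Long-format view (indicator_id, compartment_id, score) for export."""
    long = scores.stack().rename("score").reset_index()
    long.columns = ["compartment_id", "indicator_id", "score"]
    return long[["indicator_id", "compartment_id", "score"]]
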