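"""Plot-survey input/output and Braun-Blanquet cover handling.

Phytosociological relevés record, for each plot, the species present and an
ordinal Braun-Blanquet cover-abundance code.  This module reads and validates
the four tabular inputs of the assessment (surveys, species traits,
compartments, raw indicator values), converts Braun-Blanquet codes to
fractional covers via a configurable midpoint table, and pools per-plot
covers into per-compartment mean cover fractions.

All tables are UTF-8 comma-separated files with a header row and ``.``
decimal separator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "BB_CODES",
    "DEFAULT_BB_SCALE",
    "Compartment",
    "ValidationError",
    "bb_to_cover_fraction",
    "normalize_species",
    "pool_covers",
    "read_compartments",
    "read_geometries",
    "read_raw_values",
    "read_surveys",
    "read_traits",
    "write_surveys",
]

#: Ordered classic Braun-Blanquet cover-abundance codes (r = solitary
#: individuals, + = few individuals with negligible cover, 1-5 = cover
#: classes up to 5%, 25%, 50%, 75% and 100%).
BB_CODES: tuple[str, ...] = ("r", "+", "1", "2", "3", "4", "5")

#: Default code -> cover-fraction conversion (class midpoints, van der
#: Maarel-style).  Injectable wherever a ``scale`` argument is accepted so
#: alternative conventions can be used.
DEFAULT_BB_SCALE: dict[str, float] = {
    "r": 0.001,
    "+": 0.005,
    "1": 0.025,
    "2": 0.15,
    "3": 0.375,
    "4": 0.625,
    "5": 0.875,
}

SURVEY_COLUMNS = ("plot_id", "compartment_id", "species", "bb")
TRAIT_COLUMNS = ("species", "vpa", "height_m")
COMPARTMENT_COLUMNS = ("id", "cover", "management", "area_ha")
RAW_VALUE_COLUMNS = ("indicator_id", "compartment_id", "value", "orientation", "assessable")


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class Compartment:
    """A contiguous land-cover x management unit of the study area.

    The four classic classes (managed/natural forest, managed/natural
    grassland) are instances of this type, not hard-coded categories.
    """

    id: str
    cover: str  # "forest" | "grassland"
    management: str  # "managed" | "natural"
    area_ha: float
    geometry: BaseGeometry | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.cover not in ("forest", "grassland"):
            raise ValidationError(
                f"compartment {self.id!r}: cover must be 'forest' or 'grassland', got {self.cover!r}"
            )
        if self.management not in ("managed", "natural"):
            raise ValidationError(
                f"compartment {self.id!r}: management must be 'managed' or 'natural', "
                f"got {self.management!r}"
            )
        if not self.area_ha > 0:
            raise ValidationError(f"compartment {self.id!r}: area_ha must be > 0, got {self.area_ha}")

    @property
    def area_m2(self) -> float:
        """Compartment surface S_c in square metres."""
        return self.area_ha * 10_000.0


def normalize_species(name: str) -> str:
    """Canonical species key: whitespace-collapsed, case-folded.

    No taxonomic synonym resolution is attempted.
    """
    return " ".join(str(name).split()).casefold()


def bb_to_cover_fraction(bb: str, scale: Mapping[str, float] | None = None) -> float:
    """Convert one Braun-Blanquet code to its midpoint cover fraction.

    The default table is strictly increasing over the code order
    r < + < 1 < 2 < 3 < 4 < 5 and maps into (0, 1].
    """
    table = DEFAULT_BB_SCALE if scale is None else scale
    code = str(bb).strip()
    if code not in table:
        raise ValidationError(
            f"invalid Braun-Blanquet code {bb!r} (expected one of {sorted(table)})"
        )
    return float(table[code])


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def read_surveys(
    path: str | Path,
    compartments: Iterable[Compartment] | None = None,
    scale: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Read and validate a plot-survey table.

    Columns: ``plot_id, compartment_id, species, bb``.  Every BB code must
    be in the (possibly injected) conversion table; ``(plot_id, species)``
    must be unique; each plot must belong to exactly one compartment.  When
    ``compartments`` is given, referential integrity of ``compartment_id``
    is checked.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SURVEY_COLUMNS, f"survey table {path}")
    df = df.loc[:, list(SURVEY_COLUMNS)].copy()
    if df.empty:
        return df

    table = DEFAULT_BB_SCALE if scale is None else scale
    df["bb"] = df["bb"].str.strip()
    bad = df.index[~df["bb"].isin(table)]
    if len(bad):
        row = int(bad[0])
        raise ValidationError(
            f"invalid Braun-Blanquet code {df.at[row, 'bb']!r} in row {row + 2} of {path}"
        )

    df["species"] = df["species"].map(normalize_species)
    dup = df.duplicated(subset=["plot_id", "species"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValidationError(
            f"duplicate (plot_id, species) = "
            f"({df.at[row, 'plot_id']!r}, {df.at[row, 'species']!r}) in {path}"
        )

    plot_comp = df.groupby("plot_id")["compartment_id"].nunique()
    multi = plot_comp[plot_comp > 1]
    if len(multi):
        raise ValidationError(
            f"plot(s) assigned to more than one compartment: {sorted(multi.index)}"
        )

    if compartments is not None:
        known = {c.id for c in compartments}
        unknown = sorted(set(df["compartment_id"]) - known)
        if unknown:
            raise ValidationError(f"unknown compartment_id(s) in surveys: {unknown}")
    return df


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    """Serialize a survey table; inverse of :func:`read_surveys`."""
    df.loc[:, list(SURVEY_COLUMNS)].to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a species trait table (``species, vpa, height_m``).

    VPA is the dimensionless potential allergenic value in [0, 1]; height
    is the mean mature height in metres (> 0).  Species names are
    normalized to the same canonical key used for surveys.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, f"trait table {path}")
    df = df.loc[:, list(TRAIT_COLUMNS)].copy()
    df["species"] = df["species"].map(normalize_species)
    if df["species"].duplicated().any():
        dups = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValidationError(f"duplicate species in trait table: {dups}")
    if ((df["vpa"] < 0) | (df["vpa"] > 1)).any():
        raise ValidationError("vpa must lie in [0, 1]")
    if (df["height_m"] <= 0).any():
        raise ValidationError("height_m must be > 0")
    return df.set_index("species")


def read_geometries(path: str | Path) -> dict[str, BaseGeometry]:
    """Read compartment polygons from a GeoJSON FeatureCollection.

    Each feature carries the compartment identifier in its ``id`` property.
    Multiple features with the same id are unioned (a compartment may be
    several disjoint polygons).
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms: dict[str, BaseGeometry] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        cid = props.get("id")
        if cid is None:
            raise ValidationError(f"{path}: feature without an 'id' property")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValidationError(f"{path}: invalid geometry for compartment {cid!r}")
        geoms[cid] = geom if cid not in geoms else geoms[cid].union(geom)
    return geoms


def read_compartments(
    csv_path: str | Path, geojson_path: str | Path | None = None
) -> list[Compartment]:
    """Read the compartment table, optionally attaching GeoJSON polygons."""
    df = pd.read_csv(csv_path)
    _require_columns(df, COMPARTMENT_COLUMNS, f"compartment table {csv_path}")
    if df["id"].duplicated().any():
        raise ValidationError(f"duplicate compartment id(s) in {csv_path}")
    geoms = read_geometries(geojson_path) if geojson_path is not None else {}
    out = [
        Compartment(
            id=str(r.id),
            cover=str(r.cover),
            management=str(r.management),
            area_ha=float(r.area_ha),
            geometry=geoms.get(str(r.id)),
        )
        for r in df.itertuples()
    ]
    unknown = sorted(set(geoms) - {c.id for c in out})
    if unknown:
        raise ValidationError(f"geometry for unknown compartment id(s): {unknown}")
    return out


def read_raw_values(path: str | Path) -> pd.DataFrame:
    """Read the per-compartment raw indicator magnitudes.

    Columns: ``indicator_id, compartment_id, value, orientation,
    assessable``.  Orientation is ``ES`` (service) or ``ED`` (disservice).
    Non-assessable rows carry an empty value; assessable values must be
    >= 0 (magnitudes — the ED sign convention is applied during scoring).
    """
    df = pd.read_csv(path)
    _require_columns(df, RAW_VALUE_COLUMNS, f"raw value table {path}")
    df = df.loc[:, list(RAW_VALUE_COLUMNS)].copy()
    if df.duplicated(subset=["indicator_id", "compartment_id"]).any():
        raise ValidationError(f"duplicate (indicator, compartment) row(s) in {path}")
    if not df["orientation"].isin(["ES", "ED"]).all():
        raise ValidationError("orientation must be 'ES' or 'ED'")
    df["assessable"] = df["assessable"].astype(bool)
    bad = df["assessable"] & (df["value"].isna() | (df["value"] < 0))
    if bad.any():
        raise ValidationError("assessable rows must carry a value >= 0")
    if (~df["assessable"] & df["value"].notna()).any():
        raise ValidationError("non-assessable rows must not carry a value")
    return df


def pool_covers(
    surveys: pd.DataFrame,
    compartment: Compartment | str,
    scale: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-species mean cover fraction over all plots of one compartment.

    Absence of a species from a plot counts as zero cover, so the pooled
    value for each species is (sum of its plot fractions) / (number of
    plots in the compartment) — plots are equal-area random samples of the
    compartment, hence the unweighted arithmetic mean.

    Returns a Series indexed by species name, values in [0, 1], sorted by
    species for determinism.
    """
    cid = compartment.id if isinstance(compartment, Compartment) else compartment
    sub = surveys[surveys["compartment_id"] == cid]
    if sub.empty:
        raise ValidationError(f"no survey data for compartment {cid!r}")
    n_plots = sub["plot_id"].nunique()
    fractions = sub["bb"].map(lambda b: bb_to_cover_fraction(b, scale))
    pooled = fractions.groupby(sub["species"]).sum() / n_plots
    pooled.name = "cover"
    return pooled.sort_index()
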