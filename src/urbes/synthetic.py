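"""Synthetic study areas and the reference-study fixture.

``simulate_study`` generates a complete, internally consistent input bundle
— rectangular compartment polygons, 400 m² plot surveys with
Braun-Blanquet codes, a species trait table (VPA, mean height) and a raw
indicator-value table — with the statistical structure the assessment
assumes: communities drawn from a Dirichlet distribution with a
configurable evenness, i-Tree-style indicators drawn from class-dependent
ranges (grasslands non-assessable for the six canopy-model indicators),
and diversity/allergenicity indicators computed from the generated surveys
themselves.

``rbc_fixture`` loads the fixed reference bundle: the printed
per-compartment magnitudes of a 106.2 ha Mediterranean urban park split
into managed/natural forest and grassland (MF/NF/MG/NG), together with the
expected score matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .allergenicity import allergenicity_table
from .diversity import diversity_table
from .scoring import RBC_INDICATORS, Indicator
from .surveys import (
    DEFAULT_BB_SCALE,
    Compartment,
    ValidationError,
    read_compartments,
    read_raw_values,
)

__all__ = ["SimulationConfig", "StudyBundle", "simulate_study", "rbc_fixture", "write_bundle"]

#: Upper bounds of the cover classes matching the default midpoint table;
#: used to discretize continuous covers back to Braun-Blanquet codes.
_BB_UPPER = (("r", 0.002), ("+", 0.01), ("1", 0.05), ("2", 0.25), ("3", 0.5), ("4", 0.75), ("5", 1.0))

#: Class-dependent uniform ranges for the externally modelled indicators
#: (magnitudes bracketing a temperate-Mediterranean urban forest).  ``None``
#: marks a non-assessable cover type.
DEFAULT_VALUE_RANGES: dict[str, dict[str, tuple[float, float] | None]] = {
    "carbon_storage": {"forest": (200.0, 300.0), "grassland": None},
    "gross_sequestration": {"forest": (7000.0, 8200.0), "grassland": None},
    "net_sequestration": {"forest": (6400.0, 7600.0), "grassland": None},
    "avoided_runoff": {"forest": (2000.0, 3500.0), "grassland": None},
    "oxygen_production": {"forest": (18000.0, 19500.0), "grassland": None},
    "pollution_removal": {"forest": (50.0, 70.0), "grassland": None},
    "uv_reduction": {"forest": (80.0, 95.0), "grassland": (1.0, 2.0)},
    "voc_emission": {"forest": (6500.0, 9500.0), "grassland": None},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study area.

    Defaults mirror the reference study conditions: one compartment per
    land-cover x management class with areas 49.3/38.2/3.9/14.8 ha and 52
    plots of 400 m² split 24/19/3/6 among them.
    """

    seed: int = 0
    #: (id, cover, management, area_ha) per compartment.
    compartments: tuple[tuple[str, str, str, float], ...] = (
        ("MF", "forest", "managed", 49.3),
        ("NF", "forest", "natural", 38.2),
        ("MG", "grassland", "managed", 3.9),
        ("NG", "grassland", "natural", 14.8),
    )
    #: Plots per compartment, aligned with ``compartments``; ``None`` means
    #: allocate ``n_plots_total`` proportionally to area (largest remainder,
    #: at least one plot each).
    plots_per_compartment: tuple[int, ...] | None = (24, 19, 3, 6)
    n_plots_total: int = 52
    species_pool: int = 120
    #: Species per compartment community, by cover type.
    community_richness: Mapping[str, int] = field(
        default_factory=lambda: {"forest": 40, "grassland": 20}
    )
    species_per_plot: int = 15
    #: Dirichlet concentration of community relative abundances; large
    #: values give even communities (H' -> ln k).
    evenness: float = 1.0
    #: Total fractional plant cover a plot may reach, by cover type.
    canopy_bound: Mapping[str, float] = field(
        default_factory=lambda: {"forest": 0.9, "grassland": 0.8}
    )
    #: Lognormal sigma of plot-to-plot cover noise.
    plot_noise: float = 0.3
    #: Multiplier on drawn ES magnitudes for managed compartments (managed
    #: stands tend to out-provision natural ones for most canopy services).
    managed_es_boost: float = 1.08
    #: Fraction of the species pool that are trees (taller, woody).
    tree_fraction: float = 0.4
    value_ranges: Mapping[str, Mapping[str, tuple[float, float] | None]] = field(
        default_factory=lambda: DEFAULT_VALUE_RANGES
    )

    def validate(self) -> None:
        if not self.compartments:
            raise ValidationError("config must declare at least one compartment")
        if self.species_pool < 1 or self.species_per_plot < 1:
            raise ValidationError("species counts must be >= 1")
        if self.species_per_plot > self.species_pool:
            raise ValidationError(
                f"species_per_plot ({self.species_per_plot}) exceeds the "
                f"species pool ({self.species_pool})"
            )
        for cover, k in self.community_richness.items():
            if k > self.species_pool:
                raise ValidationError(
                    f"community richness for {cover!r} ({k}) exceeds the species pool"
                )
        if self.plots_per_compartment is not None and len(self.plots_per_compartment) != len(
            self.compartments
        ):
            raise ValidationError("plots_per_compartment length mismatch")
        if any(a <= 0 for *_ids, a in self.compartments):
            raise ValidationError("compartment areas must be > 0")
        if not self.evenness > 0:
            raise ValidationError("evenness must be > 0")


@dataclass
class StudyBundle:
    """A complete set of assessment inputs plus provenance metadata."""

    compartments: list[Compartment]
    surveys: pd.DataFrame | None
    traits: pd.DataFrame | None
    raw_values: pd.DataFrame
    score_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    indicators: tuple[Indicator, ...] = RBC_INDICATORS
    meta: dict = field(default_factory=dict)


def _allocate_plots(config: SimulationConfig) -> list[int]:
    if config.plots_per_compartment is not None:
        return list(config.plots_per_compartment)
    areas = np.array([a for *_ids, a in config.compartments], dtype=float)
    quota = config.n_plots_total * areas / areas.sum()
    counts = np.maximum(1, np.floor(quota).astype(int))
    while counts.sum() < config.n_plots_total:
        counts[np.argmax(quota - counts)] += 1
    while counts.sum() > config.n_plots_total:
        over = np.where(counts > 1, counts - quota, -np.inf)
        counts[np.argmax(over)] -= 1
    return counts.tolist()


def _fraction_to_bb(fraction: float) -> str | None:
    if fraction <= 0:
        return None
    for code, upper in _BB_UPPER:
        if fraction <= upper:
            return code
    return "5"


def _layout_geometries(config: SimulationConfig, gap_m: float = 100.0) -> list:
    """Axis-aligned rectangles of the required areas, laid out in a row."""
    geoms = []
    x = 0.0
    height = 500.0
    for *_ids, area_ha in config.compartments:
        width = area_ha * 10_000.0 / height
        geoms.append(box(x, 0.0, x + width, height))
        x += width + gap_m
    return geoms


def _simulate_surveys(
    config: SimulationConfig, rng: np.random.Generator, compartments: Sequence[Compartment]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    pool = [f"species_{i:03d}" for i in range(config.species_pool)]
    n_trees = int(round(config.tree_fraction * config.species_pool))
    heights = np.concatenate(
        [rng.uniform(5.0, 30.0, size=n_trees), rng.uniform(0.2, 2.0, size=config.species_pool - n_trees)]
    )
    vpa = rng.beta(2.0, 5.0, size=config.species_pool)
    traits = pd.DataFrame({"species": pool, "vpa": vpa, "height_m": heights}).set_index("species")

    plot_counts = _allocate_plots(config)
    rows: list[dict] = []
    plot_no = 0
    for comp, n_plots in zip(compartments, plot_counts):
        k = int(config.community_richness.get(comp.cover, config.species_per_plot))
        members = rng.choice(config.species_pool, size=k, replace=False)
        abundance = rng.dirichlet(np.full(k, config.evenness))
        bound = float(config.canopy_bound.get(comp.cover, 0.9))
        per_plot = min(config.species_per_plot, k)
        for _ in range(n_plots):
            plot_no += 1
            plot_id = f"p{plot_no:03d}"
            chosen = rng.choice(k, size=per_plot, replace=False, p=abundance)
            jitter = rng.lognormal(0.0, config.plot_noise, size=per_plot)
            covers = abundance[chosen] * jitter
            covers *= bound / max(covers.sum(), 1e-12)
            entries = []
            for idx, cov in zip(chosen, covers):
                code = _fraction_to_bb(float(cov))
                if code is not None:
                    entries.append([pool[members[idx]], code])
            # enforce the canopy bound on the midpoint-converted covers
            order = {c: i for i, (c, _u) in enumerate(_BB_UPPER)}
            codes = [c for _c, _u in _BB_UPPER for c in [_c]]
            while entries and sum(DEFAULT_BB_SCALE[c] for _s, c in entries) > bound:
                j = max(range(len(entries)), key=lambda i: order[entries[i][1]])
                pos = order[entries[j][1]]
                if pos == 0:
                    entries.pop(j)
                else:
                    entries[j][1] = codes[pos - 1]
            for sp, code in entries:
                rows.append(
                    {"plot_id": plot_id, "compartment_id": comp.id, "species": sp, "bb": code}
                )
    surveys = pd.DataFrame(rows, columns=["plot_id", "compartment_id", "species", "bb"])
    return surveys, traits


def _simulate_raw_values(
    config: SimulationConfig,
    rng: np.random.Generator,
    compartments: Sequence[Compartment],
    surveys: pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    div = diversity_table(surveys, compartments).set_index("compartment_id")
    alg = allergenicity_table(surveys, traits, compartments).set_index("compartment_id")
    rows = []
    for comp in compartments:
        rows.append(
            {"indicator_id": "shannon", "compartment_id": comp.id,
             "value": div.at[comp.id, "shannon"], "orientation": "ES", "assessable": True}
        )
    for ind_id, ranges in config.value_ranges.items():
        orientation = "ED" if ind_id == "voc_emission" else "ES"
        for comp in compartments:
            rng_pair = ranges.get(comp.cover)
            if rng_pair is None:
                rows.append(
                    {"indicator_id": ind_id, "compartment_id": comp.id, "value": np.nan,
                     "orientation": orientation, "assessable": False}
                )
            else:
                lo, hi = rng_pair
                value = rng.uniform(lo, hi)
                if orientation == "ES" and comp.management == "managed":
                    value *= config.managed_es_boost
                rows.append(
                    {"indicator_id": ind_id, "compartment_id": comp.id, "value": value,
                     "orientation": orientation, "assessable": True}
                )
    for comp in compartments:
        rows.append(
            {"indicator_id": "allergenicity", "compartment_id": comp.id,
             "value": alg.at[comp.id, "index"], "orientation": "ED", "assessable": True}
        )
    return pd.DataFrame(rows, columns=["indicator_id", "compartment_id", "value", "orientation", "assessable"])


def simulate_study(config: SimulationConfig | None = None) -> StudyBundle:
    """Generate a reproducible synthetic input bundle from one seed.

    The bundle passes all input validations, the grassland compartments are
    non-assessable for the six canopy-model indicators, and the Shannon and
    allergenicity rows of the raw-value table are computed from the
    generated surveys so the whole bundle is internally consistent.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    geoms = _layout_geometries(config)
    compartments = [
        Compartment(cid, cover, mgmt, area_ha, geometry=geom)
        for (cid, cover, mgmt, area_ha), geom in zip(config.compartments, geoms)
    ]
    surveys, traits = _simulate_surveys(config, rng, compartments)
    raw = _simulate_raw_values(config, rng, compartments, surveys, traits)
    return StudyBundle(
        compartments=compartments,
        surveys=surveys,
        traits=traits,
        raw_values=raw,
        meta={"seed": config.seed, "generator": "urbes.synthetic.simulate_study"},
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write a bundle to CSV + GeoJSON files in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle.surveys is not None:
        bundle.surveys.to_csv(outdir / "surveys.csv", index=False)
    if bundle.traits is not None:
        bundle.traits.reset_index().to_csv(outdir / "traits.csv", index=False)
    pd.DataFrame(
        [
            {"id": c.id, "cover": c.cover, "management": c.management, "area_ha": c.area_ha}
            for c in bundle.compartments
        ]
    ).to_csv(outdir / "compartments.csv", index=False)
    feats = [
        {"type": "Feature", "properties": {"id": c.id}, "geometry": mapping(c.geometry)}
        for c in bundle.compartments
        if c.geometry is not None
    ]
    with open(outdir / "compartments.geojson", "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
    bundle.raw_values.to_csv(outdir / "raw_values.csv", index=False)
    if bundle.score_overrides:
        pd.DataFrame(
            [
                {"indicator_id": i, "compartment_id": c, "score": s}
                for (i, c), s in bundle.score_overrides.items()
            ]
        ).to_csv(outdir / "score_overrides.csv", index=False)
    with open(outdir / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.meta, fh, indent=1)


def rbc_fixture() -> tuple[StudyBundle, pd.DataFrame]:
    """The reference-study bundle and its expected score matrix.

    The raw-value table holds the study's printed per-compartment
    magnitudes; the compartments are simple rectangles with the published
    areas (49.3/38.2/3.9/14.8 ha).  The allergenicity column carries score
    overrides: the published scores were standardized from unrounded
    indices, so they cannot be recovered exactly from the 2-decimal printed
    index values, and the managed-grassland raw index was never printed at
    all.  The expected matrix holds the published scores verbatim,
    including the per-compartment averaged ES-ED score.
    """
    root = resources.files("urbes.data") / "rbc"
    with resources.as_file(root) as path:
        compartments = read_compartments(path / "compartments.csv", path / "compartments.geojson")
        raw = read_raw_values(path / "raw_values.csv")
        over = pd.read_csv(path / "score_overrides.csv")
        expected = pd.read_csv(path / "expected_scores.csv").set_index("compartment_id")
        totals = pd.read_csv(path / "totals.csv")
    overrides = {
        (r.indicator_id, r.compartment_id): float(r.score) for r in over.itertuples()
    }
    bundle = StudyBundle(
        compartments=compartments,
        surveys=None,
        traits=None,
        raw_values=raw,
        score_overrides=overrides,
        meta={
            "study_area": "RBC urban park, 106.2 ha assessed",
            "carbon_storage_totals_Mg": {
                r.compartment_id: float(r.value) for r in totals.itertuples()
            },
        },
    )
    return bundle, expected
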