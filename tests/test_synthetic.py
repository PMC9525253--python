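"""Synthetic study-area generator: determinism, structure, recoverability."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from urbes import (
    DEFAULT_BB_SCALE,
    SimulationConfig,
    ValidationError,
    rbc_fixture,
    read_compartments,
    read_raw_values,
    read_surveys,
    read_traits,
    shannon_index,
    simulate_study,
    standardize,
    write_bundle,
)
from urbes.surveys import pool_covers
from urbes.synthetic import _allocate_plots


class TestSimulateStudy:
    def test_same_seed_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            write_bundle(simulate_study(SimulationConfig(seed=42)), tmp_path / sub)
        for name in ("surveys.csv", "traits.csv", "compartments.csv",
                     "compartments.geojson", "raw_values.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_study(SimulationConfig(seed=0))
        b = simulate_study(SimulationConfig(seed=1))
        assert not a.surveys.equals(b.surveys)

    def test_default_plot_split_matches_study_design(self):
        bundle = simulate_study(SimulationConfig(seed=3))
        counts = bundle.surveys.groupby("compartment_id")["plot_id"].nunique()
        assert counts.to_dict() == {"MF": 24, "NF": 19, "MG": 3, "NG": 6}
        assert bundle.surveys["plot_id"].nunique() == 52

    def test_proportional_allocation(self):
        config = SimulationConfig(seed=0, plots_per_compartment=None, n_plots_total=52)
        counts = _allocate_plots(config)
        assert sum(counts) == 52
        assert all(c >= 1 for c in counts)
        assert counts[0] > counts[1] > counts[3] > counts[2]  # ordered by area

    def test_outputs_pass_input_validations(self, tmp_path):
        bundle = simulate_study(SimulationConfig(seed=7))
        write_bundle(bundle, tmp_path)
        comps = read_compartments(tmp_path / "compartments.csv", tmp_path / "compartments.geojson")
        surveys = read_surveys(tmp_path / "surveys.csv", comps)
        traits = read_traits(tmp_path / "traits.csv")
        raw = read_raw_values(tmp_path / "raw_values.csv")
        assert set(s for s in surveys["species"]) <= set(traits.index)
        grass = {c.id for c in comps if c.cover == "grassland"}
        canopy_rows = raw[raw["indicator_id"] == "carbon_storage"]
        assert not canopy_rows[canopy_rows["compartment_id"].isin(grass)]["assessable"].any()
        for c in comps:
            assert c.geometry.area == pytest.approx(c.area_m2, rel=1e-9)

    def test_canopy_bound_respected_per_plot(self):
        config = SimulationConfig(seed=5)
        bundle = simulate_study(config)
        fr = bundle.surveys["bb"].map(DEFAULT_BB_SCALE)
        totals = fr.groupby(bundle.surveys["plot_id"]).sum()
        comp_of_plot = bundle.surveys.drop_duplicates("plot_id").set_index("plot_id")["compartment_id"]
        cover_of = {c.id: c.cover for c in bundle.compartments}
        for plot_id, total in totals.items():
            bound = config.canopy_bound[cover_of[comp_of_plot[plot_id]]]
            assert total <= bound + 1e-9

    def test_high_evenness_approaches_max_entropy(self):
        """H' of even communities nears ln k, within plot-subsampling error.

        Each plot records only `species_per_plot` of the k community members,
        so even a perfectly even community pools to a multinomial sample whose
        expected entropy deficit is about (k - 1) / (2 N) for N records, on
        top of Braun-Blanquet quantization noise.
        """
        even_h, uneven_h = [], []
        for seed in range(5):
            even = simulate_study(SimulationConfig(seed=seed, evenness=1e4, plot_noise=0.0))
            uneven = simulate_study(SimulationConfig(seed=seed, evenness=0.3, plot_noise=0.0))
            for comp in even.compartments:
                pooled = pool_covers(even.surveys, comp)
                h, ln_k = shannon_index(pooled), math.log(len(pooled))
                even_h.append(h)
                assert h > 0.85 * ln_k
                uneven_h.append(shannon_index(pool_covers(uneven.surveys, comp)))
        assert np.mean(even_h) > np.mean(uneven_h)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValidationError, match="species_per_plot"):
            simulate_study(SimulationConfig(seed=0, species_pool=10, species_per_plot=20))
        with pytest.raises(ValidationError, match="richness"):
            simulate_study(SimulationConfig(seed=0, species_pool=10, species_per_plot=5))

    def test_injected_ranking_recovered(self):
        bundle = simulate_study(SimulationConfig(seed=13))
        scores = standardize(bundle.raw_values, bundle.indicators, bundle.score_overrides)
        raw = bundle.raw_values
        for ind_id in scores.columns:
            sub = raw[(raw["indicator_id"] == ind_id) & raw["assessable"]]
            injected = sub.set_index("compartment_id")["value"]
            got = scores.loc[injected.index, ind_id].abs()
            assert (injected.rank() == got.rank()).all()


class TestRbcFixture:
    def test_areas_sum(self, rbc):
        bundle, _ = rbc
        assert sum(c.area_ha for c in bundle.compartments) == pytest.approx(106.2)

    def test_expected_average_scores(self, rbc):
        _, expected = rbc
        assert expected["averaged_es_ed"].tolist() == [0.614, 0.590, 0.003, 0.054]

    def test_mg_allergenicity_is_override_not_raw(self, rbc):
        bundle, _ = rbc
        raw = bundle.raw_values
        row = raw[(raw["indicator_id"] == "allergenicity") & (raw["compartment_id"] == "MG")]
        assert not row["assessable"].item()
        assert bundle.score_overrides[("allergenicity", "MG")] == -0.287

    def test_loads_reproducibly(self):
        b1, e1 = rbc_fixture()
        b2, e2 = rbc_fixture()
        pd.testing.assert_frame_equal(b1.raw_values, b2.raw_values)
        pd.testing.assert_frame_equal(e1, e2)
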