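"""Score standardization, ED sign handling and the averaged ES-ED score."""

import numpy as np
import pandas as pd
import pytest

from urbes import (
    Indicator,
    ValidationError,
    averaged_es_ed,
    per_hectare,
    standardize,
    total_from_per_hectare,
)
from urbes.scoring import scores_long


def raw_table(rows):
    return pd.DataFrame(rows, columns=["indicator_id", "compartment_id", "value", "orientation", "assessable"])


TWO_INDICATORS = [
    Indicator("svc", "service", "u", "ES"),
    Indicator("dis", "disservice", "u", "ED"),
]


class TestStandardize:
    def test_max_normalization_and_ed_sign(self):
        raw = raw_table(
            [
                ("svc", "A", 60.48, "ES", True),
                ("svc", "B", 66.75, "ES", True),
                ("dis", "A", 9140.3, "ED", True),
                ("dis", "B", 7084.9, "ED", True),
            ]
        )
        scores = standardize(raw, TWO_INDICATORS)
        assert scores.at["A", "svc"] == pytest.approx(0.906, abs=5e-4)
        assert scores.at["B", "svc"] == 1.0
        assert scores.at["A", "dis"] == -1.0
        assert scores.at["B", "dis"] == pytest.approx(-0.775, abs=5e-4)

    def test_non_assessable_cells_are_zero(self):
        raw = raw_table(
            [
                ("svc", "A", 2.0, "ES", True),
                ("svc", "B", np.nan, "ES", False),
                ("dis", "A", 5.0, "ED", True),
                ("dis", "B", np.nan, "ED", False),
            ]
        )
        scores = standardize(raw, TWO_INDICATORS)
        assert scores.at["B", "svc"] == 0.0
        assert scores.at["B", "dis"] == 0.0

    def test_ties_all_score_one(self):
        raw = raw_table([("svc", "A", 3.0, "ES", True), ("svc", "B", 3.0, "ES", True)])
        scores = standardize(raw, TWO_INDICATORS[:1])
        assert (scores["svc"] == 1.0).all()

    def test_idempotent_on_standardized_magnitudes(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.1, 9.0, size=4)
        raw = raw_table([("svc", f"C{i}", v, "ES", True) for i, v in enumerate(values)])
        once = standardize(raw, TWO_INDICATORS[:1])
        again = standardize(
            raw_table([("svc", c, once.at[c, "svc"], "ES", True) for c in once.index]),
            TWO_INDICATORS[:1],
        )
        pd.testing.assert_frame_equal(once, again)

    def test_all_zero_column_rejected(self):
        raw = raw_table([("svc", "A", 0.0, "ES", True), ("svc", "B", 0.0, "ES", True)])
        with pytest.raises(ValidationError, match="no positive maximum"):
            standardize(raw, TWO_INDICATORS[:1])

    def test_override_fills_unassessable_cell(self):
        raw = raw_table(
            [
                ("dis", "A", 5.0, "ED", True),
                ("dis", "B", np.nan, "ED", False),
            ]
        )
        scores = standardize(raw, TWO_INDICATORS[1:], overrides={("dis", "B"): -0.287})
        assert scores.at["B", "dis"] == -0.287
        assert scores.at["A", "dis"] == -1.0

    def test_column_extrema(self):
        rng = np.random.default_rng(9)
        raw = raw_table(
            [("svc", f"C{i}", v, "ES", True) for i, v in enumerate(rng.uniform(1, 9, 5))]
            + [("dis", f"C{i}", v, "ED", True) for i, v in enumerate(rng.uniform(1, 9, 5))]
        )
        scores = standardize(raw, TWO_INDICATORS)
        assert scores["svc"].max() == 1.0
        assert scores["dis"].min() == -1.0
        assert scores["svc"].between(0, 1).all()
        assert scores["dis"].between(-1, 0).all()


class TestAveragedScore:
    def test_published_mf_row(self):
        row = [1.000, 0.978, 1.000, 1.000, 1.000, 1.000, 0.906, 1.000, -1.000, -0.740]
        scores = pd.DataFrame([row], index=["MF"], columns=[f"i{k}" for k in range(10)])
        assert averaged_es_ed(scores)["MF"] == pytest.approx(0.614, abs=5e-4)

    def test_mostly_zero_row(self):
        row = [0.305, 0, 0, 0, 0, 0, 0, 0.013, 0, -0.287]
        scores = pd.DataFrame([row], index=["MG"], columns=[f"i{k}" for k in range(10)])
        assert round(averaged_es_ed(scores)["MG"], 3) == 0.003

    def test_all_zero_row_is_zero(self):
        scores = pd.DataFrame([[0.0] * 10], index=["X"], columns=[f"i{k}" for k in range(10)])
        assert averaged_es_ed(scores)["X"] == 0.0

    def test_bounded_and_equals_row_mean(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.uniform(-1, 1, size=(6, 10)))
        avg = averaged_es_ed(scores)
        assert np.allclose(avg, scores.mean(axis=1))
        assert avg.between(-1, 1).all()

    def test_uniform_weights_match_default(self):
        scores = pd.DataFrame([[0.4, -0.2]], index=["A"], columns=["x", "y"])
        assert averaged_es_ed(scores, {"x": 1, "y": 1})["A"] == averaged_es_ed(scores)["A"]
        assert averaged_es_ed(scores, {"x": 3, "y": 1})["A"] == pytest.approx(
            (3 * 0.4 - 0.2) / 4
        )

    def test_empty_indicator_set_rejected(self):
        with pytest.raises(ValidationError, match="empty indicator set"):
            averaged_es_ed(pd.DataFrame(index=["A"]))


class TestUnitConversion:
    def test_per_hectare_round_trip(self):
        assert per_hectare(10.4e3, 38.2) == pytest.approx(272.25, abs=0.01)
        assert total_from_per_hectare(per_hectare(123.4, 7.7), 7.7) == pytest.approx(123.4)

    def test_one_hectare_identity(self):
        assert per_hectare(42.0, 1.0) == 42.0

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValidationError):
            per_hectare(1.0, 0.0)
        with pytest.raises(ValidationError):
            total_from_per_hectare(1.0, -2.0)


def test_scores_long_round_trip():
    scores = pd.DataFrame(
        [[0.5, -0.2]], index=pd.Index(["A"], name="compartment_id"), columns=["x", "y"]
    )
    long = scores_long(scores)
    assert set(long.columns) == {"indicator_id", "compartment_id", "score"}
    assert len(long) == 2
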