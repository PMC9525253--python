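"""End-to-end convenience wrappers over the assessment stages."""

from __future__ import annotations

import pandas as pd

from .mapping import ScoreRaster, average_rasters, rasterize_scores
from .scoring import averaged_es_ed, standardize
from .synthetic import StudyBundle

__all__ = ["score_bundle", "map_bundle"]


def score_bundle(bundle: StudyBundle) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize a bundle's raw values and average them.

    Returns the signed score matrix (compartments x indicators) and the
    per-compartment averaged ES-ED score.
    """
    scores = standardize(bundle.raw_values, bundle.indicators, bundle.score_overrides)
    return scores, averaged_es_ed(scores)


def map_bundle(
    bundle: StudyBundle, cell_size: float = 1.0
) -> tuple[dict[str, ScoreRaster], ScoreRaster]:
    """Rasterize every indicator's scores and their cellwise average."""
    scores, _ = score_bundle(bundle)
    rasters = {
        ind.id: rasterize_scores(
            bundle.compartments, scores[ind.id].to_dict(), cell_size, indicator_id=ind.id
        )
        for ind in bundle.indicators
    }
    return rasters, average_rasters(list(rasters.values()))
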