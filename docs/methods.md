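# Methods

This note records the assessment model as implemented, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data can and cannot demonstrate.

## Survey handling and the Braun-Blanquet conversion

Relevés are 400 m² plots, each belonging to exactly one compartment, with
one ordinal cover-abundance code per species.  The classic 7-code scale
(r, +, 1–5) is assumed; extended variants (2m/2a/2b) are not parsed.  The
code → fraction conversion uses class midpoints:

| code | r | + | 1 | 2 | 3 | 4 | 5 |
|------|---|---|---|---|---|---|---|
| fraction | 0.001 | 0.005 | 0.025 | 0.15 | 0.375 | 0.625 | 0.875 |

No single convention is universal in the literature, so the table is an
injectable parameter of every conversion entry point; the default is the
midpoint (van der Maarel-style) convention, strictly increasing over the
code order.  Pooling across a compartment's plots is the unweighted
arithmetic mean with absences counted as zero cover — plots are equal-area
random samples, so the mean is the unbiased estimate of compartment-level
cover.  Species names are matched case-insensitively after whitespace
normalization; synonym resolution is out of scope.

## Shannon–Wiener diversity

H′ = −Σ pᵢ ln pᵢ with natural logarithm (the ecological default), where
pᵢ are pooled mean covers renormalized to sum to one.  One H′ is reported
per compartment (pooled covers, not a mean of per-plot indices).  The
implementation drops zero-cover species (0 ln 0 := 0) and rejects
all-zero communities.  Display rounding is 2 decimals; full precision is
kept for scoring.

## modI_UGZA

The index is the literal sum Σ VPAᵢ·SBBᵢ·Hᵢ normalized by
maxH·maxVPA·S_c, with maxima taken over the species found in that
compartment (not globally).  SBBᵢ is operationalized as pooled cover
fraction × S_c, which makes the index unit-free in S_c and bounds it by 1
without any truncation: the bound is attained only by a single species at
full cover.  Degenerate all-VPA-zero communities return 0 (the numerator
vanishes); the denominator uses a 10⁻⁹ VPA floor to avoid 0/0, and the
condition is logged.  Risk classification is inclusive (index ≥ 0.3
counts as at risk), so a compartment exactly at the threshold is flagged.
Heights are mean mature heights from the trait table; no growth modelling.

## Scoring

Per indicator, scores are value / max-over-compartments, so every column
attains 1 (ties all score 1); ED columns are then negated.  Cells that
cannot be assessed — in the reference study, the six canopy-model
indicators on grassland — score 0 and remain in the denominator of the
per-compartment mean over all N indicators.  Including them is a modelling
choice, not an artifact: a compartment that provides no measurable canopy
service should be pulled toward neutrality, and it is what makes the
grassland averages reproducible.  Weights default to uniform; a weight
vector is accepted.  Scores are stored at full precision and reported at
3 decimals.

A score-override channel carries cells whose standardized score is known
while the raw magnitude is not.  The packaged reference fixture uses it
for the whole allergenicity column: the published scores were evidently
standardized from unrounded indices, and the rounded 2-decimal indices
that are available cannot reproduce them to 3 decimals (0.56/0.75 gives
−0.747 where −0.740 was published; the managed-grassland index was never
published at all, only its −0.287 score).  All other columns are computed
from the raw magnitudes.  With or without the overrides, the four averaged
ES–ED scores agree with the published 0.614 / 0.590 / 0.003 / 0.054 at
3 decimals.

One internal inconsistency of the reference values is preserved as-is:
the managed-forest carbon total (11.2×10³ Mg over 49.3 ha) implies
227.2 Mg ha⁻¹, not the published 266.5.  The fixture stores the published
per-hectare values and the totals separately and derives nothing from
that division.

## Rasterization

Cell assignment uses cell-center containment (all-touched = false), the
unbiased area rule; the discretization error of mapped area is bounded by
one cell width along the compartment boundary, and is zero when polygon
edges align with the grid (the fixture's rectangles at 1 m).  The grid
origin snaps outward to integer multiples of the cell size.  Coordinates
must be metric; a CRS string that looks geographic (EPSG:4326 etc.) is
rejected because square-metre cells are undefined in degrees.  Nodata is
NaN in memory and −9999 on disk; output is ESRI ASCII (plain text, ~10
significant digits), with an optional diverging-colormap PNG quick-look.
Averaging requires co-registered grids and propagates nodata from any
layer; inside the mapped area every layer is defined because unassessed
scores are zeros.  Compartments are processed in sorted id order for
reproducibility; overlapping polygons are an error.

The default cell size is 1 m.  Tests and examples use 10 m cells, which
exercise identical code paths on ~10⁴ cells instead of ~10⁶; the 1 m
fixture raster (1,062,000 mapped cells) runs in a few seconds.

## Synthetic data

The generator emulates the reference study conditions: four compartments
(MF/NF/MG/NG) with areas 49.3/38.2/3.9/14.8 ha as adjacent rectangles,
and 52 plots split 24/19/3/6 (the study's own allocation; exact
proportional allocation by largest remainder, used when no explicit split
is given, would yield 24/19/2/7).  Communities are drawn per compartment
from a Dirichlet with concentration `evenness` over a 120-species pool
(forest communities 40 species, grassland 20 — plausible relevé richness,
far below a full park flora); each plot records 15 species sampled by
abundance, with lognormal plot-to-plot noise (σ = 0.3), discretized to BB
codes by class bounds and then down-coded greedily until the
midpoint-converted total cover respects the canopy bound (0.9 forest, 0.8
grassland).  VPA ~ Beta(2, 5) (most species weakly allergenic), heights
uniform on 5–30 m for the 40 % tree fraction and 0.2–2 m otherwise.
Externally modelled indicators are drawn from uniform ranges bracketing
the reference magnitudes, with grassland non-assessable for the six
canopy indicators and a ×1.08 boost for managed compartments' ES (managed
stands out-provisioned natural ones for most services).  A single seeded
`numpy` generator threads through all draws; the seed is stored in the
bundle metadata and identical seeds produce byte-identical bundles.

What passing synthetic tests shows: the pipeline preserves injected
orderings (standardization is strictly monotone), validations compose,
and diversity behaves as entropy should.  What it does not show: realism
of species composition, spatial autocorrelation within compartments,
correlated indicator errors, or any fidelity of the uniform indicator
ranges to a real park — the generator is a structural emulator, not an
ecological model.  Even-community entropy converges to ln k only up to
plot-subsampling (≈ (k−1)/2N) and BB-quantization deficits, which the
tests bound explicitly.

## Numerical conventions and limitations

- Natural-log entropy; 1e−12 tolerances on exact identities (entropy
  maxima, index-vs-oracle, raster commutation).
- Polygon overlap tolerance 1e−6 m² (shapely exact predicates otherwise).
- The i-Tree Eco model itself, VPA derivation from pollen biology,
  monetary valuation and cartographic styling are out of scope; raw
  indicator magnitudes are inputs.
- The CLI is a thin wrapper; exit codes 0/1/2 for success / validation /
  I/O.
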