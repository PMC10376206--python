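# Methods

## The cumulative impact model

The package maps the cumulative negative impact of invasive and
cryptogenic species on marine habitats over a regular latitude/longitude
lattice. Each cell receives the score

    I_c = Σ_i Σ_j  A_i · H_j · w_ij

where, per cell,

* **A_i** is the standardized population state of species *i* on [0, 1]:
  binary presence from occurrence records, or a continuous habitat
  suitability produced by an upstream distribution-model ensemble;
* **H_j** is the fractional cover of habitat type *j* (a fraction on
  [0, 1], not a 0–100 percentage, which keeps the product dimensionless
  and bounded);
* **w_ij ≥ 0** is the impact weight of species *i* on habitat *j*.

The model is purely additive: no interaction or saturation terms, no
temporal dynamics, and no uncertainty propagation over the weight
classes. Its value lies in the exact decomposability — the per-cell
score splits exactly by species, habitat type, and biotic group, which
is what the disaggregation and ranking machinery exploits.

## Grid and habitat conventions

The lattice defaults to 0.01° cells (roughly 1 km at Mediterranean
latitudes), indexed row-major from the northwest corner with half-open
cell boundaries (a point on an interior shared edge belongs to the
east/south neighbour; the last row/column is closed). Cell areas are
treated as equal in degree space: every downstream statistic counts
cells, so no geodesic correction is applied anywhere.

Ten habitat types are tracked: nine benthic (seagrass meadows, soft and
hard substrates split at 60 m and 200 m depth, submarine caves,
coralligenous formations) plus the pelagic water column. Types at
0–200 m are *coastal*, types below 200 m *open sea*; the pelagic
habitat belongs to both zones and is assigned full cover on every
study-area cell. Because the pelagic layer has H = 1 everywhere, the
per-cell Σ_j H_j can reach 2; that is intentional — the water column
overlays the seabed rather than competing with it for area.

Benthic cover is the exact degree-space area fraction of the habitat's
unioned polygons within each cell. Overlapping polygons of one habitat
are unioned before intersection (no double counting); overlaps between
different benthic habitats are tolerated at read time but flagged when
a cell's benthic sum exceeds 1 + 1e-6, since real habitat maps (e.g.
coralligenous formations over hard substrate) do overlap. Cover
fractions below 1e-12 are treated as zero: at cell areas of order 1e-4
square degrees such values are floating-point slivers from polygon
unions, and keeping them would silently inflate habitat support counts.

## Impact weights

Each documented impact carries an ordinal magnitude class (EICAT-style,
minimal → massive) and an ordinal evidence-strength class (weak →
strong). A configurable matrix maps (magnitude, evidence) to a numeric
weight; the *uncertainty-averse* rule resolves multiple documented
impacts of one species on one habitat to the maximum weight — the worst
documented impact governs. Pairs with no documented impact have weight
zero.

The vocabularies and the numeric grid deliberately ship as
configuration, not code: the engine enforces only non-negativity,
ordinality, and monotonicity of weight in magnitude at fixed evidence,
so revised weighting schemes drop in without code changes. The packaged
default grid sets weight = 1-based magnitude rank irrespective of
evidence — a valid degenerate case of the uncertainty-averse scheme
that keeps every hand calculation in the tests exact.

## Disaggregations and indicators

Habitat shares divide each habitat's summed score by the grand total;
the per-habitat mean divides the habitat's summed score by the number
of cells where the habitat occurs (H_j > 0). The exact standardization
of published per-habitat means is a genuinely open choice, so a
cover-weighted variant (divide by Σ H_j instead of the support count)
is exposed behind a flag; the support-count mean is the default because
it answers "how hard is an average occupied cell hit", independent of
how fragmentary the cover is.

Five species indicators are computed:

* **D1** — occupied cells: distinct masked cells with ≥ 1 record;
* **D2** — impacted cells: cells with per-species score strictly > 0
  (strict, no epsilon);
* **D3a / D3b** — summed score over the study area from the modelled
  and the record-based score maps respectively;
* **D4** — mean score over the species' range of occurrence, excluding
  cells scoring strictly below 0.1. A cell at exactly 0.1 is kept, and
  the "range of occurrence" is operationalized as exactly the surviving
  cells (any other reading double-filters). D4 is *undefined* (NaN),
  not zero, when no cell qualifies, and undefined values are unranked.

D2 and D4 use the modelled score maps by default (falling back to
record-based maps for species without a model); a switch flips them to
record-based maps throughout. Rankings are descending with rank 1 the
most impactful; ties break lexicographically by species id so rankings
are reproducible. Excluded species keep their values but carry no rank.

The North/South regional split is a configurable boundary latitude with
no scientific default (the fixture uses the grid midline); cells are
assigned by centroid latitude, south being strictly below the boundary.
A boundary outside the extent yields a degenerate but valid partition
rather than an error.

## Synthetic seascapes

The generator produces study inputs with the structure the analysis
consumes, not a replica of any real sea:

* **Bathymetry** — a smooth west-to-east offshore ramp
  (300·t^1.5 m over the normalized longitude t) plus Gaussian-filtered
  seeded noise (σ = 3 cells, 25 m amplitude), stratifying cells into
  the 0–60 m, 60–200 m and > 200 m classes at roughly 35/40/25%.
* **Habitat mosaic** — benthic habitats grow as randomized flood-fill
  patches (target ~40 cells each) inside their depth class until target
  fractions of the seabed are met; patches are mutually exclusive, so
  benthic covers sum to ≤ 1 by construction, and patch rim cells get
  cover 0.7 so fractional percent-cover semantics are exercised.
* **Records** — per in-range cell a Poisson count with mean
  `record_intensity` (default 0.5), multiplied by `south_bias` in the
  southern region; positions uniform within the cell.
* **Suitability** — an isotropic Gaussian kernel (σ = 0.12° by default)
  around a planted center, multiplied by a ramp rising from 1 at the
  northern edge to `south_bias` at the southern edge, clipped to [0, 1].
* **Evidence** — every species×impacted-habitat pair draws a magnitude
  class; one designated worst species (the first invertebrate, planted
  with a study-wide range, a broad kernel and impacts on the pelagic
  plus every benthic habitat) receives the top magnitude class
  throughout, while all others draw strictly below it. The planted
  ground-truth ordering sorts by (max magnitude rank, number of
  impacted habitats).

Every output is a pure function of (config, seed); each generator stage
draws from its own seeded substream so adding species does not perturb
the seascape.

The default scenario is a 50×50-cell (0.5°×0.5°) seascape with six
species over the three biotic groups. The `south_hotspot` preset uses
`south_bias = 4` with species centers planted in the southern half and
a high-score threshold of 8 — roughly the score level only reachable
where several species overlap benthic habitat, given default weights of
1–5. The `uniform` preset removes the bias; `empty` has no species and
exercises the all-zero paths. These sizes keep a full scenario run
around 0.1 s, so replicate studies (100 seeds) remain cheap.

What passing tests on these seascapes show — and what they do not: the
generator validates the pipeline's arithmetic, bookkeeping, planted-
signal recovery and reproducibility. It does not emulate spatial
sampling bias, autocorrelated survey effort, coastline geometry,
habitat mapping error, or mis-georeferenced records, so passing tests
say nothing about robustness to those real-data pathologies.

## Numerical choices

* Point-in-cell assignment snaps coordinates to cell boundaries at
  relative tolerance 1e-9 before flooring, so records on an exact edge
  land deterministically (east/south neighbour).
* An extent that is not an integer number of cells is expanded outward
  (anchored at the southwest corner) to the next cell boundary.
* The total score accumulates per-species maps in sorted species order,
  making the result bitwise independent of layer input order.
* Shares over a zero grand total are reported as undefined (NaN), never
  0/0; the same convention applies to D4 and to high-score fractions
  when no cell exceeds the threshold.
* Min–max rescaling of a constant suitability raster maps to all zeros
  with a warning (the degenerate range has no information).
* All floating-point CSV output is written with 9 significant digits;
  GeoTIFF layers are float32, so file-based and in-memory results agree
  to ~1e-7 relative.

## Known limitations

* Additivity is assumed, as in the underlying index family; co-occurring
  species' impacts simply sum.
* Degree-space cell equality ignores the ~20% meridional variation of
  cell area across a large domain; acceptable for cell-counting
  statistics, wrong for km² reporting.
* The records→binary presence route inherits survey effort bias; the
  generator does not simulate it, see above.
* GeoTIFF support covers the single-band north-up WGS84 layout this
  pipeline writes; it is not a general GeoTIFF reader.
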