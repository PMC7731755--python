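# Methods

## Setting and model

The toolkit links point-located survey clusters to health facilities when
the cluster coordinates have been randomly displaced for privacy and the
facility coordinates have not. The linkable unit throughout is the
*facility unit*: a hospital or health center together with every
lower-level service point (health post, village clinic, outreach post)
that names it as parent. Lower-level posts are never linked directly —
with ~9000 posts against ~600 facilities, per-post linkage would make the
district join meaningless — but they contribute twice: their locations
shape the unit's catchment, and their (kind, operator) pairs count toward
type-matching.

### Theoretical catchment areas

Thiessen (Voronoi) cells are computed around **all** service points —
facility-level and posts alike — and dissolved by owning unit. The result
is a tessellation of the study region into non-overlapping catchments, one
per unit, each containing all of the unit's sites. A unit whose posts are
separated by another unit's territory gets a multi-part catchment; this is
recorded, not rejected. NGO- and private-operated units participate in the
tessellation (deleting their sites would artificially enlarge their
neighbours' catchments) but are excluded from linkage by the default
candidate filter, which keeps the public system: government plus CHAM
(publicly funded, NGO-administered) units. The filter is a parameter
(`public` / `all`).

### The four joins

For a cluster at observed location `s` (projected meters):

* **closest** — the single candidate unit minimizing the Euclidean
  distance to its facility point; ties (within 1e-9 m) go to the smallest
  facility id.
* **buffer(r)** — all candidate units with facility point within `r`
  (inclusive); clusters may be left with an empty link set, which is kept.
* **admin** — all candidate units whose facility point carries the
  cluster's district id. Assignment is by attribute, not re-derived
  spatially, because surveys guarantee displacement stays in-district.
* **catchment(r)** — all candidate units whose catchment polygon is within
  `r` of `s` (point-to-polygon distance, 0 when inside). At `r = 0` this
  is exactly the containing catchment; `r = 5 km` absorbs the standard
  rural displacement.

Buffer and catchment link sets are monotone in `r`, and the closest unit
is always contained in a non-empty buffer set with the same candidates.

### Evaluation

Per method: number and percent of clusters with ≥1 link; mean and
population SD of link-set sizes (headline over linked clusters only — the
alternative including zero-link clusters is also computed, since published
practice is ambiguous); and appropriateness — the share of eligible women
(modern-contraception users reporting one of the four linkable source
categories) whose cluster links at least one unit offering the matching
(kind, operator): government hospital, government health center,
government health post, or — for the collapsed CHAM category — any
CHAM-operated member at any level. The overall row is the count-weighted
average of the per-source rates, an exact identity before rounding;
rounding (half-up, printed precision) happens only at render time.
Appropriateness is an upper bound on linking a woman to the facility she
actually used; on synthetic data the generator's ground truth also yields
the exact true-source-linked rate, which is reported alongside.

## Geometry

* **Projection**: spherical azimuthal equidistant about the data centroid,
  earth radius 6 371 000 m. Distances from the center are exact; over a
  ±400 km extent local distance error is far below 0.5%, negligible
  against 2–10 km displacement scales. The projector is pluggable (any
  object with `forward`/`inverse`), so a national grid (e.g. UTM 36S) can
  be substituted for real data. Near-polar inputs (|lat| ≥ 89.9°) are
  rejected.
* **Bounded Voronoi**: scipy's diagram is closed by eight ghost sites on a
  ring 100× the region span, which forces every real cell finite; cells
  are then clipped to the region polygon, so they tile it exactly (tested
  to 1e-6 relative area). Sites closer than 1 m are treated as coincident:
  `voronoi_partition` refuses them, and the catchment builder pools them
  into one site first (the cell goes to the unit of the smallest pooled
  id).
* **Distances**: inclusive (≤) boundaries everywhere; point-in-polygon
  distance is 0 on the boundary.

## Displacement simulation

Angle ~ Uniform(0, 2π), distance ~ Uniform(0, d_max) with d_max = 5 km
rural, 10 km for an independent Bernoulli(1%) subset of rural clusters,
2 km urban. The radial-uniform distance follows published survey
displacement practice (the procedure itself is documented only as "up
to"); it gives E[d] = d_max/2, which the tests verify by Monte Carlo.
Containment in the cluster's own district is enforced by rejection
sampling that re-draws *both* angle and distance, preserving the marginal
distribution conditional on containment; a cluster in a sliver polygon
that exhausts `max_attempts` (default 10 000) raises an error naming the
cluster rather than silently truncating.

## Synthetic landscape

The generator emulates the structure the analysis assumes, at the
documented study scale by default: a 250 × 850 km rectangle (elongated,
so district-boundary effects resemble a long thin country) split into 28
Voronoi districts; 85 hospitals + 542 health centers (450 government, 145
CHAM, remainder NGO) with 8870 posts multinomially allotted to parents and
scattered around them with exponential distance decay (scale 3 km, capped
at 15 km); 817 rural clusters; ~12.9 women per cluster (rounded Gamma,
shape 4). Facilities and clusters are drawn from a shared density surface
— 4 urban foci plus 60 rural settlement foci (Gaussian σ 4.5 km, 85%
weight, remainder uniform). The settlement scale was set so that roughly
65% of displaced clusters fall within 5 km of a public facility point,
reproducing the documented low-density access regime in which buffer
linkage loses a third of the clusters; NGO operators are weighted 9:1
toward urban-component facilities, and hospitals 4:1, mirroring where
such facilities cluster in practice.

Respondents: modern use ~ Bernoulli(44.75%); users report an unlinkable
source (community agents, NGO outlets, private clinics, shops) with
probability 19.56%; otherwise the true source unit is the unit owning the
catchment of the cluster's *true* location with probability `p_home`
(default 0.85, a free bypassing parameter — no empirical value is
documented), else a uniformly random other public unit. A respondent whose
home catchment is NGO/private-owned reports an unlinkable source (people
in an NGO catchment use the NGO facility, which is off the linkable list);
the urban bias of NGO units keeps this inflation small, and the
calibration tests check the Bernoulli rates on the exact subpopulations
they govern. The reported source *category* is drawn from the chosen
unit's available kinds, weighted 4948 : 2287 : 552 (health center :
hospital : post) to match the documented respondent mix; any CHAM unit
yields the collapsed CHAM category. Contraceptive-method labels are drawn
from configurable mixes (defaults reproduce the documented included /
ineligible method tables). Ground truth — the exact unit each linkable
woman used — is retained for oracle evaluation.

What the generator does **not** emulate: real road networks and
travel-time access, urban sampling, enumeration-area frames, facility
opening/closing between survey waves, or spatially correlated reporting
error. Passing tests therefore demonstrate correctness of the linkage
machinery and directionally realistic method comparisons, not
Malawi-specific magnitudes: linked-cluster shares and method orderings
reproduce the documented regime closely, while quantities dominated by
micro-geography (e.g. mean facilities per buffer) differ from any specific
country.

## Numerical and design choices

* Size factor: `LandscapeParams.scaled(f)` shrinks counts and the
  country length together, preserving densities; tests run mostly at
  f = 0.05–0.1 (tens of units) with study-scale runs (f = 1, ~9500 Voronoi
  sites, a few seconds) in the acceptance checks and the directional
  5-seed comparison.
* Determinism: a single integer seed drives every random draw (numpy
  `default_rng`); identical config + seed reproduce byte-identical CSVs.
* Ties and boundaries: inclusive everywhere; closest-facility ties broken
  lexicographically; cluster exactly on a catchment edge at radius 0 may
  link both adjacent units (measure-zero event under continuous
  coordinates).
* Degenerate inputs rejected with typed errors: dangling parent ids,
  unknown enum tokens, out-of-range coordinates, unclosed GeoJSON rings,
  self-intersecting polygons, empty candidate sets, sliver-district
  displacement.

## Known limitations

* Catchments are *theoretical*: Voronoi proximity stands in for true
  service areas; travel time, terrain and facility capacity are ignored.
* The spherical projection is adequate at national extents but should be
  replaced by a proper grid for continental-scale data.
* Appropriateness matches facility *types*, so it remains an upper bound
  on true linkage; the true-source-linked metric exists only where ground
  truth does (simulation).
* The admin join trusts the district attribute; clusters displaced across
  a boundary in violation of the stated procedure would be mis-joined.
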