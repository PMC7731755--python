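# catchlink

Geospatial linkage of displaced household-survey clusters to health
facilities, including the **theoretical catchment area** method built from
Thiessen (Voronoi) polygons.

## The problem

Household surveys such as the DHS release cluster GPS coordinates only
after random displacement (rural clusters moved up to 5 km, 1% up to
10 km, urban up to 2 km, always within the true district). Health-facility
master lists are released undisplaced. Studies of effective coverage need
to join the two: which facilities does each surveyed community plausibly
use? The classical indirect joins — nearest facility, all facilities within
a 5 km buffer, all facilities in the same district — trade off data loss,
precision, and correctness in different ways, and all of them suffer when
coordinates are displaced.

This package implements those three joins plus a fourth: each hospital or
health center **H** and its affiliated lower-level service points (health
posts, village clinics, outreach posts) are treated as one *facility unit*;
Thiessen polygons are built around *every* service point and dissolved by
owning unit, giving a non-overlapping tessellation of the country into
theoretical catchment areas `C(H)`. A cluster with observed (displaced)
location `s` is linked to every unit whose catchment comes within radius
`r` of the cluster:

```
links(s) = { H : d(s, C(H)) ≤ r },      r = 5 km by default
```

so a displaced cluster still reaches the catchment it truly lies in for all
but the rare long-range displacements. Linkage quality is evaluated by (i)
the share of clusters linked at all, (ii) the mean (SD) number of
facilities linked per cluster, and (iii) the share of modern-contraception
users whose cluster is linked to at least one facility of the *type* they
last reported as their source (government hospital / health center / health
post, or any CHAM facility — CHAM is collapsed into one source category).

Because the real survey coordinates and master list are restricted, the
package ships a full synthetic landscape generator (districts, facility
hierarchy, DHS-style displacement, respondents with known true source
facility), so every method can be validated against exact ground truth —
something impossible with real displaced data.

## Worked example

Simulate a study-scale landscape (28 districts, 85 hospitals + 542 health
centers + 8870 posts, 817 rural clusters), displace the clusters, build
catchments, run all four methods, and print the comparison report:

```bash
catchlink compare --out-dir results/demo --seed 1
```

Abridged output (one row per method):

```
   method  n_linked  pct_linked  mean_links  sd_links  overall_pct_appropriate  pct_true_source_linked
  closest       817       100.0         1.0      0.00                     71.6                    37.5
   buffer       525        64.3         2.5      1.38                     58.3                    40.4
    admin       817       100.0        28.7     14.91                     99.8                    80.2
catchment       816        99.9         4.8      2.32                     97.8                    85.1
```

Reading the table: the 5 km buffer loses a third of the clusters entirely
(64.3% linked) and matches women to their reported source type worst
(58.3%), because displacement pushes clusters out of small buffers. The
district join links everything but at the cost of ~29 facilities per
cluster — a homogeneous, uninformative service environment. The catchment
method keeps nearly every cluster (99.9%), links only ~5 units each, and
still matches 97.8% of women to their reported source type. The last
column uses the simulator's ground truth: the catchment method links 85.1%
of women to the *actual* unit they used, against 37.5% for
nearest-facility — the displacement-robustness the method is designed for.

The same stages are available individually (`catchlink simulate`,
`catchlink displace`, `catchlink build-catchments`, `catchlink link
--method {closest,buffer,admin,catchment}`) and as library functions
(`catchlink.linkage`, `catchlink.catchments`, `catchlink.evaluation`).

## Layout

```
src/catchlink/
  model.py        domain types (service points, facility units, clusters, ...)
  geodata_io.py   CSV/GeoJSON readers and writers, hierarchy validation
  geometry.py     projection, distances, bounded Voronoi, dissolve
  catchments.py   theoretical catchment construction
  linkage.py      the four linking methods
  displacement.py DHS-style displacement simulation
  synthetic.py    synthetic landscape generator
  evaluation.py   comparison metrics and reports
  cli.py          command-line interface
docs/methods.md   model, assumptions, parameters, limitations
```
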