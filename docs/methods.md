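# Methods

## Model overview

`redna-kit` treats a region as a triple: a road network (planar meter
coordinates, per-edge length and free-flow speed, optional one-way flags), a
set of inhabited grid cells anchored to network nodes (population count, a
7-class urban–rural regional label RS71–RS77, an administrative unit), and a
set of treatment facilities anchored to nodes (linac count). All travel is by
car; edge travel time is `length_m / (speed_kmh * 1000/60)` minutes. The
toolkit never performs geodetic datum math — user-supplied coordinates must
already be projected to meters.

### Travel-cost matrix

For every facility, two single-source Dijkstra searches (time-weighted and
distance-weighted) run on the *reversed* directed graph, so matrix entries
are costs of travel **from cell to facility**; on networks without one-way
edges the direction is immaterial. Each entry stores the optimised quantity
exactly and the companion quantity (route km along the fastest path, route
minutes along the shortest path) accumulated along the returned optimal path;
when several optimal paths tie, the companion belongs to one of them.
Unreachable pairs carry `inf`, are flagged with a structured warning, and are
excluded from downstream statistics with a logged count. Costs stay in double
precision until report formatting (minutes/km and percents to 1 decimal,
utilization to 3 decimals).

The full dense matrix is kept in memory, guarded by a configurable size limit
(default 10⁷ entries; `cost_matrix(..., max_entries=...)` raises beyond it).
Facility rankings can be truncated to the top *k* per cell; redistribution
falls back to a dense argmin when a truncated ranking is exhausted, so a
truncated ranking never changes a result. An automatic sparse top-k-only
store for above-limit matrices is not implemented — at the scales this
toolkit targets the dense form always fits.

Reported travel times are pure driving times. A flat access/egress/parking
offset can be added as post-processing (`CostMatrix.with_offset(5.0)`,
CLI `--offset-min 5`); it defaults to **off**, since both conventions appear
in practice and the offset shifts every time statistic uniformly.

### Catchments and accessibility statistics

A facility's catchment is the set of cells whose rank-1 facility it is under
a chosen criterion (time or distance) among the currently open set; ties
break by ascending facility id, so catchments are an exclusive partition.
Real catchments overlap where facilities compete — overlap modelling is out
of scope by design.

Statistics are population-weighted: mean = Σwv/Σw, and quantiles use the
**lower (inverse-CDF) weighted definition** — the q-quantile is the smallest
observed value v with cumulative weight(≤v) ≥ q·Σw. This matches the natural
reading of "q% of the population reach a facility within v" and always
returns an observed cost; interpolated definitions can differ by up to one
cell's cost spacing. An unweighted per-cell ("area") mode is exposed for
area-averaged readings (`--weighting area`); population weighting is the
default everywhere.

### Workload model

Annual demand in malignant-equivalent cases:

    MEC(pop) = demand_scale * pop * (malignant_per_100k + benign_per_100k / benign_equivalence) / 100000

Defaults: 250 malignant and 320 benign courses per 100k inhabitants per year,
3 benign courses ≡ 1 malignant-equivalent (MEBC), `demand_scale = 1`
(values below 1 emulate, e.g., widespread hypofractionation without modelling
fractionation explicitly). Capacity is capped at 800 MEC per linac per year —
roughly a 14–15-hour working day, the upper bound of what an existing center
can absorb; utilization above 1.0 is flagged, never clipped.

All demand arithmetic is real-valued internally. Two integer-report
conventions coexist in published national tables and both are exposed:
per-linac workload figures truncate (201,615/645 → 312; 258,946/645 → 401;
MEBC 401.47/3 → 133, so the per-linac total is 312 + 133 = 445 MEC), while
residents-per-resource tables round to nearest (1,535,275/4 → 383,819).
Truncating benign/3 per linac gives 133 even though 258,946/3/645 rounds to
134 and the national MEBC total (258,946/3 ≈ 86,315 ≈ 134/linac) is sometimes
quoted as 136 per linac; the 445 = 312 + 133 decomposition is the arithmetic
this package reproduces, and the discrepancy is surfaced here rather than
resolved.

### ReDNA — closure stress test

Each facility is closed in turn; closures are independent (the baseline is
restored between iterations). Every cell of the closed facility's catchment
moves to its minimum-travel-**time** open facility — redistribution always
uses the time criterion, the choice a displaced patient would make, even when
baseline catchments were distance-based (a config override exists). For each
receiving facility the relative patient increase
`100 × added / baseline` is classified:

| level | increase | interpretation |
|---|---|---|
| 1 | [0, 10]% | minor workload change |
| 2 | (10, 25]% | compensable by longer working hours |
| 3 | (25, 50]% | compensable by additional workforce |
| 4 | (50, ∞)% | substantial change in medical management |

The published level wording ("0–10%", "10–25%", "25–50%", ">50%") leaves the
boundary values ambiguous; intervals here are **closed on the right**, so
">50%" is exactly level 4. The bounds are a documented module constant. A
receiver with an empty baseline catchment absorbing population is reported as
level 4 with an infinite-increase flag rather than a division error.
Receivers are additionally checked against the 800-MEC/linac cap after
absorption. Travel penalties per closure are population-weighted statistics
of (new − old) minutes and of the per-cell relative increase over displaced
cells with a positive baseline time.

Only single-facility closures are analysed; overflow is never cascaded to a
third facility (the engine's `open_set` signature admits multi-closure
experiments, but the headline report does not). Cluster-level exceedance
aggregation is deliberately left at the receiving-facility level — it is the
only level with an unambiguous definition.

## Synthetic scenario generator

The generator emulates a scaled-down country. Defaults (all overridable via
`SynthParams`):

| parameter | default | meaning |
|---|---|---|
| `lattice_n` | 40 | 40×40 road lattice (1600 nodes) |
| `spacing_m` | 2000 m | edge length → 80 km × 80 km domain |
| `speed_classes_kmh` | 50 (p=.5), 80 (.3), 100 (.2) | i.i.d. per-edge speeds: streets, country roads, arterials |
| `n_urban_centers` | 3 | Gaussian population kernels |
| `urban_sigma_m` | 6000 m | kernel dispersion |
| `rural_density` | 20 | mean rural inhabitants per cell |
| `total_population` | 4.8 M | preserves ≈128k residents/linac at 20 facilities × ~1.9 linacs |
| `n_facilities` | 20 | facility sites, sampled ∝ population without replacement |
| `linac_pmf` | 133/337, 128/337, 55/337, 21/337 for 1–4 | national census; the 3-linac stratum is the remainder 337−133−128−21=55, and "4 or more" is modelled as exactly 4 |
| `region_quantile_cuts` | .05, .15, .30, .50, .70, .85 | density-quantile cuts RS71→RS77 |
| `n_admin_units` | 4 | vertical admin stripes (state analogues) |

Populations are drawn Poisson around the kernel intensity and then
integer-rescaled (largest-remainder) to sum exactly to `total_population` —
inhabitants are integers, as in a census grid. Region labels come from
quantiles of the *smoothed* intensity, not the noisy draw, so stratification
follows settlement structure; the typology is a stand-in for
transport-ministry products — only the stratification behaviour matters
here, not the official derivation. All randomness flows from the single
`seed` through named substreams, so scenarios are byte-identical across runs.
A single national linac distribution is used for all admin units; no
per-state distributions are published.

What the generator does **not** emulate: real road topology (it is a
lattice), inhomogeneous cell sizes, age- or region-specific incidence,
cross-border flows, islands, and the long tail of the real linac-count
distribution (capped at 4). Passing tests therefore demonstrate the
*correctness of the machinery* on country-like structure, not calibration to
any real region; at 20 facilities a single catchment is a large share of any
receiver's capacity, so level-4 classifications and cap exceedances are much
more frequent than in a network of several hundred centers.

## Numerical and interface choices

- Ties anywhere (equal costs, equal ranks) break by ascending facility id —
  deterministic and documented.
- Unreachable cells: excluded from statistics with a logged count, reported
  in `unassigned`/`unreachable_population` fields, never dropped silently.
- Scenario CSV schemas (`nodes/edges/cells/facilities.csv`) are validated on
  read with file/row/column-precise errors; write→read is an identity on
  generated scenarios. GeoJSON export writes plain Point features.
- The CLI (`redna-kit synth|matrix|access|redna`) is a thin layer over the
  library; a flat YAML config mirrors the options and explicit flags win.

## Problem sizes

The default test and acceptance runs use the 40×40-lattice scenario
(1600 cells × 20 facilities = 32,000 matrix entries, 80 Dijkstra runs) and
complete in seconds; property suites cross-check ≥100 random graphs of ≤8
nodes against exhaustive simple-path enumeration and ≥100 random weighted
samples against a scan oracle.

## Known limitations

- Exclusive nearest-facility catchments ignore patient choice and capacity
  feedback; commercial network affiliations that redirect patients elsewhere
  than the second-closest center are not modelled.
- No cascading overflow: a receiver pushed past its cap does not shed
  patients onward.
- No turn restrictions, time-of-day speeds, or public-transport routing.
- Incidence is spatially uniform per inhabitant; regions with older
  populations will be underestimated.
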