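# redna-kit

Spatial accessibility analysis and closure stress-testing of radiotherapy
facility networks.

## The problem

External-beam radiotherapy is delivered at radiation oncology centers (ROCs)
housing one or more linear accelerators (linacs). Access to treatment is
largely a question of *spatial* accessibility: how long a patient must drive
to reach the closest — or, after a local disruption (flood, fire, cyberattack,
staffing collapse), the *second*-closest — center. `redna-kit` implements the
full analysis chain for this question, for health-services researchers and
capacity planners:

1. **Travel-cost matrix** — car travel time and route distance from every
   inhabited population-grid cell to every facility over a weighted road
   network (Dijkstra), under both the fastest-route and shortest-route
   criteria, with per-cell *n*-closest facility rankings.
2. **Workload model** — population converted to annual radiotherapy demand in
   malignant-equivalent cases (MEC): with incidence rates of 250 malignant and
   320 benign courses per 100,000 inhabitants and a 3:1 benign-to-malignant
   workload equivalence,

   `MEC(pop) = pop × (250 + 320/3) / 100 000 ≈ pop × 356.7 / 100 000`,

   compared against a sustainable cap of 800 MEC per linac per year.
3. **Accessibility statistics** — population-weighted mean, median and 95th
   percentile travel time/distance to the rank-*n* facility, stratified by a
   7-class urban–rural regional typology (RS71–RS77) or by administrative
   unit.
4. **ReDNA** (redistribution network analysis) — the stress test: each
   facility is closed in turn, its catchment reassigned to the next-closest
   open facility by travel time, and every receiving facility's relative
   patient increase is classified into four response levels
   (≤10% / ≤25% / ≤50% / >50%) and checked against the capacity cap.

Because national road/census/facility data are not redistributable, the
package ships a seeded synthetic scenario generator emulating a scaled-down
country: urban population clusters on a lattice road network with mixed speed
classes, a rural background, and facilities placed proportional to population
with the empirical national linac-count distribution (mean ≈ 1.91
linacs/facility). Real data in the documented CSV schemas drop straight in.

## Worked example

```
redna-kit synth  --seed 42 --outdir demo        # 40x40 lattice, 4.8M people, 20 facilities
redna-kit matrix --scenario demo                # (cell x facility) travel-cost matrix
redna-kit access --scenario demo                # accessibility + workload tables
redna-kit redna  --scenario demo                # closure stress test
```

`demo/access_stats.csv` then starts:

```
group_key,group,rank,criterion,weighting,mean_time_min,median_time_min,p95_time_min,mean_dist_km,median_dist_km,p95_dist_km,population
ALL,ALL,1,time,population,7.7,6.9,17.1,9.4,8.0,22.0,4800000
ALL,ALL,2,time,population,11.8,11.1,22.2,14.7,14.0,28.0,4800000
region_type,RS71,1,time,population,4.5,4.2,9.0,5.4,6.0,10.0,1108642
```

Reading the first row: averaged over all 4.8 M synthetic inhabitants, the
time-closest facility is 7.7 min away (median 6.9), and 95% of the population
reaches one within 17.1 min; losing the closest option raises the mean to
11.8 min (rank 2). The metropolitan stratum (RS71) is predictably faster
(mean 4.5 min).

`demo/redna_penalties.csv` summarises each simulated closure:

```
closed_facility_id,displaced_pop,mean_added_min,median_added_min,mean_relative_pct,unreachable_pop
f000,214713,5.1,4.2,94.5,0
f001,220625,7.3,6.3,120.5,0
```

Closing facility `f000` displaces 214,713 residents, whose drive grows by
5.1 min on average — a 94.5% mean relative increase. `demo/redna_report.csv`
gives the receiving-facility view (patient increase, response level 1–4,
post-closure MEC per linac and cap utilization); in this run the 75 receiver
rows classify as level 1/2/3/4 in 22/27/12/14 cases and 18 exceed the
800-MEC/linac cap — at 20 facilities a single catchment is a large fraction
of any receiver's capacity, so this scaled-down network is deliberately less
redundant than a national one with hundreds of centers.

The same pipeline is available as a library (`rednakit.generate_scenario`,
`rednakit.cost_matrix`, `rednakit.accessibility_table`,
`rednakit.run_full_redna`); `--config run.yaml` supplies any option as a flat
YAML document, with command-line flags taking precedence.

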