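# fullcycle

Full-annual-cycle spatial conservation prioritization for migratory
species, as a tested, end-to-end pipeline on synthetic data.

Migratory birds occupy vastly different regions across the year, yet most
conservation plans target only the breeding or wintering grounds.  This
package implements the machinery needed to plan across all 52 weeks at
once: estimating weekly relative-abundance surfaces from checklist-style
citizen-science observations, delineating regional abundance clusters
within each species-week, and selecting the cheapest set of planning
units that secures a fixed share of every species' population in every
week — then comparing the eight planning scenarios that arise from
crossing three design axes.  It is aimed at quantitative ecologists and
conservation-planning methodologists who want a transparent, fully
seeded, desk-scale implementation of the whole chain.

## The model

Reserve selection is the minimum set cover integer linear program

    minimize  c·x    subject to  A x ≥ b,   x_j ∈ {0, 1}

with decision variable `x_j` (select planning unit j), costs `c`,
representation matrix `A_ij = r_ij` (relative abundance of conservation
feature i in unit j) and targets `b_i = p · Σ_j r_ij` at target
proportion `p` (default 30%).  The eight scenarios cross:

* **weekly vs. yearly** — 52 independent problems (one feature per
  species; solutions summed into a 0–52 selection-frequency map) vs. one
  problem with every species-week as a feature;
* **single vs. clustered population** — one range-wide target per
  feature vs. targets stratified over k regional abundance clusters
  (CLARA k-medoids on min-max-scaled latitude, longitude and abundance,
  abundance down-weighted to 1/3);
* **shared-use vs. intact habitat** — uniform cost 1 vs. a 0–50
  human-footprint-style cost surface.

Abundance surfaces are estimated by a spatiotemporal ensemble: 100
randomly offset partitions of the study extent into blocks (10°/20°
squares × 30 days, smaller north of 12° latitude), one two-step model
(occupancy × conditional abundance) per block with ≥ 50 checklists and
≥ 10 detections, predictions averaged over all blocks containing a
location-date at a standardized search effort, and withheld where fewer
than 50 models contribute.  A synthetic-landscape module generates
migratory abundance cubes with conserved weekly totals, zero-inflated
effort-dependent checklist counts, bounded cost fields and categorical
land cover, so every stage runs and is tested without any data download.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
20 × 20 grid of 8.4 km cells with 5 synthetic migrants, 8 weeks sampling
the annual cycle and k = 3 clusters:

```bash
python analysis/01_simulate_landscape.py --seed 1
python analysis/02_fit_abundance.py      --seed 1
python analysis/03_cluster_abundance.py  --seed 1
python analysis/04_run_scenarios.py      --seed 1
python analysis/05_landcover_summary.py  --seed 1
```

`04_run_scenarios.py` prints (seed 1):

```
                       scenario  summed_area_km2  union_area_km2   objective  status
       weekly_single_shared_use         24484.32        11642.40  347.000000 optimal
   weekly_single_intact_habitat         31328.64        12771.36 7203.746327 optimal
    weekly_clustered_shared_use         29564.64        13759.20  419.000000 optimal
weekly_clustered_intact_habitat         34433.28        14958.72 8875.460965 optimal
       yearly_single_shared_use          6562.08         6562.08   93.000000 optimal
   yearly_single_intact_habitat          7902.72         7902.72 1840.350533 optimal
    yearly_clustered_shared_use          7549.92         7549.92  107.000000 optimal
yearly_clustered_intact_habitat          8043.84         8043.84 2176.374059 optimal

yearly planning needs 74.8% less summed area than weekly planning (mean over the four scenario pairs)
stratifying targets over abundance clusters costs 15.1% more area (shared-use, yearly)
every feature target met: max shortfall 0.00e+00
cells selected by all 8 scenarios: 26
```

Reading this: optimizing each week independently and summing the areas
(weekly) costs several times the area of a single year-wide optimization
(yearly), because the yearly problem reuses cells that serve many
species-weeks; stratifying targets across regional clusters buys
geographic representation at a ~15% area premium; and all eight scenarios
attain every feature's 30% target exactly (zero shortfall).  The
estimator driver (`02`) reports a Spearman rank correlation of 0.938
between estimated and true surfaces at 20,000 checklists, improving from
0.898 at 2,000, with MAE falling 1.8-fold.

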