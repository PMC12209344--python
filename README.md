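# scatdiet

Diet analysis for carnivore scat DNA metabarcoding, downstream of taxonomy
assignment. Given per-PCR-replicate taxon read counts, the package:

1. **filters** reads by replicate consensus — a taxon is kept when it reaches
   a relative-read-abundance threshold (default ≥ 1%) in at least 2 of 3
   valid replicates, where a replicate is valid only above a depth threshold
   (default > 1000 reads);
2. **assigns a defecator** species to each scat (sole carnivore, or dominant
   carnivore when other carnivore reads stay under 10% of the sample) and
   excludes scats with no usable diet items;
3. computes per-species diet profiles as **FOO** (frequency of occurrence)
   and **wPOO** (weighted percent of occurrence, equal scat weights split
   uniformly among detected items), with taxonomic rank aggregation;
4. estimates pairwise dietary overlap with **Pianka's index**, a
   niche-breadth-retaining **permutation null** (within-vector shuffles,
   zeros included) and a scat-bootstrap CI;
5. estimates diet richness by **incidence-based rarefaction/extrapolation**
   with the **Chao2** asymptote and bootstrap bands.

A seeded synthetic scat-read simulator (`scatdiet.synthetic_scats`) with
known ground truth — defecator-dominated counts, per-replicate dropout of
rare taxa, tag-jump reassignment, occasional second-carnivore contamination
and failed replicates — backs end-to-end validation without any external
data.

## CLI

All functionality is under one `scatdiet` command:

```sh
# synthetic dataset with ground truth
scatdiet simulate --seed 1 --n-scats 30 --out-dir sim/

# full analysis: filter -> assign -> diet metrics -> overlap -> rarefaction
scatdiet run --counts sim/counts.csv --taxonomy sim/taxonomy.csv \
    --seed 1 --out-dir results/

# individual stages
scatdiet filter  --counts sim/counts.csv --taxonomy sim/taxonomy.csv --out filtered.csv
scatdiet assign  --counts sim/counts.csv --taxonomy sim/taxonomy.csv --out assigned.csv
scatdiet diet    --counts sim/counts.csv --taxonomy sim/taxonomy.csv --rank family --out diet.csv
scatdiet overlap --counts sim/counts.csv --taxonomy sim/taxonomy.csv --seed 1 --out overlap.json
scatdiet rarefy  --counts sim/counts.csv --taxonomy sim/taxonomy.csv --seed 1 --out rarefy.csv

# simulation-based recovery study over a grid of known true overlaps
scatdiet validate --seed 1 --out validation.json
```

Thresholds live in a flat YAML config (`--config`); keys are the
`FilterConfig` field names (`min_reads_per_replicate`, `min_rra`,
`min_replicates`, `max_other_carnivore_share`, `min_item_share`,
`null_iterations`, `bootstrap_iterations`, `seed`, …). `run` writes a result
bundle (per-scat statuses, per-species FOO/wPOO tables, overlap/rarefaction
JSON) plus a manifest echoing the config and accounting for every scat by
status; identical seeds give byte-identical bundles.

## Input formats

Long-format CSV/TSV (delimiter sniffed from the header):

- counts: `scat_id, replicate, taxon_id, reads` — one row per scat ×
  replicate × taxon; zero-read rows are dropped on load.
- taxonomy: `taxon_id, class_name, order_name, family_name, genus_name,
  species_name, candidate_defecator` — the boolean flag marks carnivores
  that may have deposited a scat. Both readers take a `column_map` for
  files with different headers.

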