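# motupipe

Community analysis of fungal ITS1 amplicon surveys along environmental
gradients. The package implements, as a tested and reusable pipeline, the
full analysis chain used in hierarchical leaf/root fungal-diversity
studies: MOTU construction, consensus taxonomic assignment from BLAST hit
tables, abundance filtering, rarefaction-based richness estimation, and
presence/absence composition statistics. A synthetic-data generator with
known ground truth makes every stage testable without sequencing data.

It is written for ecologists and bioinformaticians analysing amplicon
surveys with a nested sampling design (regions > sites > plots, each plot
sampled in two habitats: leaf and root).

## Methods at a glance

- **MOTU clustering.** Reads shorter than 100 bp are removed; the rest are
  dereplicated and clustered by a deterministic greedy centroid algorithm
  at 97% identity. Identity is computed on a global Needleman–Wunsch
  alignment (match +1, mismatch −1, gap −2, terminal gaps penalised) as
  identical columns / alignment columns.
- **Consensus taxonomy.** Up to ten BLAST hits per MOTU are screened at
  identity > 90% and e-value < 1e−50. A genus needs ≥ 8 congruent hits
  (or all, when fewer remain); a species needs ≥ 6 congruent hits *and* a
  hit reaching 100 − *v*<sub>phylum</sub> percent identity, where
  *v*<sub>phylum</sub> is the phylum's mean ITS1 intraspecific
  variability (Ascomycota 2.88, Basidiomycota 4.98, Chytridiomycota 7.81,
  Glomeromycota 9.48, Zygomycota 4.13). MOTUs sharing an assigned species
  or a subject GI (> 90% identity, e-value < 1e−45) are merged;
  non-fungal MOTUs, singletons, and no-hit MOTUs under 10 reads are then
  discarded.
- **Richness.** Per sample, one sequence per MOTU is discarded (removing
  singletons), then richness is estimated by analytic rarefaction,
  E[S] = Σ<sub>m</sub> [1 − C(N−N<sub>m</sub>, d)/C(N, d)], at depth
  d = 1400 (leaf) or 500 (root). Group richness redistributes the
  unknown fraction: R<sub>ij</sub> = (N<sub>ij</sub>/N<sub>assigned</sub>)
  · ER<sub>j</sub>.
- **Composition.** Counts are rarefied and binarised; MOTUs in fewer than
  3 plots are dropped. Correspondence analysis summarises the table;
  Sørensen dissimilarities feed a PERMANOVA with sequential sums of
  squares over *region, soil pH, temperature, site-within-region*, with
  permutations restricted to within-region strata.
- **Synthetic data.** Hierarchical design (3 regions; 3/5/3 sites; 3
  plots; leaf depths 1506–15830, root 552–3622), lapse-driven
  temperatures, elevation-independent pH, a Zipf rank-abundance community
  with Gaussian temperature/pH niches, ITS1-like reads, and BLAST tables
  with controllable congruence.

## Worked example

```python
import motupipe as mp

samples, env = mp.generate_design(mp.DesignSpec(seed=1))
reference, abundance = mp.generate_community(
    mp.CommunitySpec(pool_size=300), samples, env, seed=1)

root = abundance.counts[abundance.design["habitat"] == "root"]
comp = mp.prepare_composition(root, depth=500, seed=1)
dist = mp.sorensen_dissimilarity(comp)
table = mp.permanova_nested(
    dist, abundance.design.loc[comp.index],
    terms=["region", "soil_pH", "temperature", "region:site"],
    strata="region", n_perm=199, seed=1)
print(table.round(3))
```

prints

```
             df     SS       F     R2      p
term
region        2  0.437   3.094  0.087  0.005
soil_pH       1  0.305   4.317  0.061  0.010
temperature   1  1.919  27.160  0.384  0.005
region:site   7  0.853   1.724  0.171  0.055
Residual     21  1.484     NaN  0.297    NaN
Total        32  4.997     NaN  1.000    NaN
```

Temperature dominates the root community turnover built into this
synthetic run (R² = 0.384, p = 0.005 at 199 within-region permutations),
pH explains a smaller share, and the site-within-region term is weak —
the p-values are valid despite the nesting because samples are only ever
permuted within their region.

The same objects feed the richness side:

```python
hits = mp.hits_from_table(mp.generate_blast_table(
    reference, mp.HitNoiseSpec(seed=1), ))
assigns = mp.assign_taxonomy(list(abundance.counts.columns), hits)
report = mp.richness_report(abundance, assigns)
print(report[["ER", "R_ascomycota", "R_basidiomycota"]].head(2).round(1))
```

```
                            ER  R_ascomycota  R_basidiomycota
sample
region1.site1.plot1.leaf  71.0          43.0             25.4
region1.site1.plot1.root  30.2          18.8             10.1
```

`ER` is the rarefied total MOTU richness; the group columns are the
redistribution estimates assuming unknown MOTUs contain each group in the
same proportion as phylum-assigned ones. (Values vary with the seed.)

A `motupipe` console script chains the same stages from a shell:
`motupipe simulate`, `cluster`, `assign`, `diversity`, `permanova`.

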