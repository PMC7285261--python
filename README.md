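# taxopan

Threshold clustering, phylogenomics, pangenome and trait analysis for
bacterial genome collections.

Genus-level comparative-genomics studies follow a common inference chain:
pairwise intergenomic distances (e.g. blast-based genome-to-genome
distances) are clustered into species-level clusters and broader
phylogenomic groups; a neighbor-joining tree summarizes the distances;
orthogroup tables from an orthology run are partitioned into hard core,
soft core, pangenome and strain-specific fractions; rarefaction asks
whether sampling more genomes would reveal more clusters; and selected
trait orthogroups (degradation enzymes, monooxygenases, dioxygenases)
are profiled across groups. `taxopan` implements that chain as a tested,
reusable library with a thin CLI, together with a synthetic-collection
generator so the whole pipeline can be validated end-to-end without any
genome downloads.

## Methods at a glance

* **Threshold clustering.** Agglomerative clustering where clusters *A*,
  *B* merge when at least a fraction *F* of cross pairs satisfy
  *d(a, b) ≤ T* (*F* = 0.5 behaves like average linkage). Species are
  delineated at *T* = 0.036, the distance equivalent of the conventional
  70% digital DNA–DNA hybridization (dDDH) boundary; group-level *T* is
  chosen by sweeping *T* (default 0–0.2, step 0.0005) and maximizing the
  chance-corrected Rand agreement (Hubert–Arabie adjusted Rand index)
  with a reference partition.
* **Neighbor joining.** Classical Saitou–Nei agglomeration with the
  Studier–Keppler *Q* criterion, deterministic tie-breaks, optional
  outgroup rooting, Newick I/O (trees are `dendropy.Tree` objects).
* **Pangenome fractions.** Hard core (OGs in 100% of genomes), soft core
  (OGs in ≥ *k* genomes), single-copy core, and core/pangenome/new-OG
  accumulation curves over random genome orderings (default 300),
  summarized by mean and quartiles.
* **Richness rarefaction.** Hypergeometric interpolation
  *S(m) = S_obs − Σᵢ C(n−xᵢ, m)/C(n, m)*, Chao1 unseen-cluster estimate
  *f₀*, exponential extrapolation toward *S_obs + f₀*, and percentile
  bootstrap confidence bands (default 1000 replicates, 95%).
* **Traits.** Per-group presence fractions of trait orthogroups,
  per-genome ortholog counts of a gene family, average-linkage heatmap
  ordering, and exact-identity deduplication of protein sequences.

## Worked example

```python
import taxopan as tp

params = tp.CollectionParams(seed=1, trait_ogs={"bphA1": frozenset({0, 2})})
coll = tp.simulate_collection(params)          # 10 groups x 2 species x 3 genomes

groups = tp.cluster_at_threshold(coll.distances, t=0.14, f=0.5)
species = tp.species_partition(coll.distances)  # T = 0.036
print(groups.n_clusters, tp.mri(groups, coll.truth_groups))
print(species.n_clusters, tp.mri(species, coll.truth_species))

res = tp.sweep_thresholds(coll.distances, coll.truth_groups)
print(res.optimal_range, res.optimal_mri)

print(len(tp.hard_core(coll.ortho)), coll.ortho.n_ogs)

x = tp.partition_to_abundance(species)
curve = tp.bootstrap_band(x, [10, 30, x.n, 200], n_boot=1000, seed=1)
print(curve.to_frame())
```

prints

```
10 1.0
20 1.0
(0.0995, 0.2) 1.0
300 2510
  m  estimate     ci_lo     ci_hi       regime
 10  8.544711  7.702125  8.544711 interpolated
 30 17.627119 14.448197 17.627119 interpolated
 60 20.000000 17.000000 20.000000     observed
200 20.000000 17.654923 26.014408 extrapolated
```

The 60-genome collection is built with a distance gap between groups, so
clustering at any threshold inside the gap recovers all 10 generating
groups exactly (agreement 1.0), and the species threshold 0.036 recovers
all 20 species. The sweep's optimal plateau contains 0.14. Of the 2510
orthogroups, the 300 simulated core OGs are present in every genome.
The rarefaction curve rises from 8.5 expected species at 10 genomes to
the observed 20 at 60; extrapolation is flat here because this seeded
collection happens to have no singleton species clusters, while the
bootstrap band still widens upward.

The same steps are available from the shell:

```sh
taxopan simulate --groups 10 --seed 1 --out coll/
taxopan cluster --distances coll/distances.tsv --t 0.036 --out species.tsv
taxopan sweep --distances coll/distances.tsv --reference coll/truth_groups.tsv
taxopan nj --distances coll/distances.tsv --outgroup g01s01r01 --out tree.nwk
taxopan pangenome --ortho coll/ortho_counts.tsv --replicates 300 --seed 1 --out curves.tsv
taxopan rarefy --partition species.tsv --max-m 200 --boot 1000 --seed 1 --out rarefaction.tsv
```

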