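# Methods

This note documents the statistical procedures implemented in `taxopan`,
the choices made where several reasonable definitions exist, and what
the synthetic-collection generator does and does not emulate.

## Threshold clustering of intergenomic distances

Input is a labeled symmetric matrix of pairwise intergenomic distances
in [0, 1] with zero diagonal (validated to 1e-9; the matrix is not
assumed metric). Clustering is agglomerative with a cross-pair fraction
criterion: starting from singletons, clusters *A* and *B* are mergeable
when

    |{(a, b) : a ∈ A, b ∈ B, d(a, b) ≤ T}| / (|A||B|) ≥ F.

Among mergeable pairs the one with the smallest mean cross distance is
merged first, with exact ties broken by the lexicographically smallest
member label; merging repeats until no pair is mergeable. *F* = 0.5
gives average-linkage-like behaviour, and is the default throughout.

The greedy smallest-mean-first rule with the label tie-break makes the
procedure fully deterministic. It is **not** order-independent for
arbitrary matrices: on unstructured random distances, different merge
orders can reach different terminal partitions. On gap-separated data —
every within-cluster distance below *T*, every cross-cluster distance
above — all merge orders provably coincide and recover the generating
partition; the test suite verifies both facts (order-equivalence on
gap-structured matrices by exhaustive search over merge orders for ≤ 7
genomes, and equality of the optimized incremental implementation with
a naive recompute-from-scratch reference on arbitrary matrices).

Species-level clusters use *T* = 0.036, the distance corresponding to
the conventional 70% dDDH species boundary; this mapping is taken as a
given constant, not recomputed. Group-level thresholds are chosen by
sweeping *T* over a grid (default 0 to 0.2 in steps of 0.0005, built as
integer index × step to avoid floating drift; 401 points) and scoring
each partition against a reference with the chance-corrected Rand
agreement. The optimal range is the [min, max] of the argmax set — on
gap-separated collections a plateau of thresholds attains agreement 1.

Partition agreement is the Hubert–Arabie adjusted Rand index computed
from the pairwise contingency table in integer arithmetic,
`(a − exp) / (max − exp)` with `exp` the chance expectation and `max`
the average of the two pair totals; two all-singleton (or two
single-cluster) partitions score 1 by convention. The implementation is
cross-checked against scikit-learn's `adjusted_rand_score` in the test
suite.

Pairs of named strains whose dDDH exceeds the species cutoff (default
70%) are flagged as candidate synonyms; the flag records whether the
entire confidence interval clears the cutoff, a stronger signal than a
straddling interval.

## Neighbor joining

Classical neighbor joining: at each step the pair minimizing
`Q(i, j) = (k − 2) d(i, j) − r_i − r_j` is joined, branch lengths from
the standard formulas, replacement distances
`d(u, m) = (d(i, m) + d(j, m) − d(i, j)) / 2`. *Q* is evaluated on the
upper triangle only because the two floating-point rounding orders of
`−r_i − r_j` can differ by one ulp; exact ties are broken by the
lexicographically smallest pair of node keys (a node's key is the
smallest leaf label beneath it), so the output is deterministic. Two
taxa give a single edge of the input distance, three taxa the
three-point closed form. Negative branch lengths, which NJ produces on
non-additive input, are clamped to zero and the deficit logged; on
additive matrices NJ is exact, which the tests use as an oracle
(path-length recovery to 1e-9, topology agreement with scikit-bio's
independent implementation).

Outgroup rooting places the root at the midpoint of the outgroup's
pendant edge, leaving the ingroup topology and all leaf-to-leaf path
lengths unchanged. Trees are `dendropy.Tree` objects; Newick I/O is
dendropy's.

## Pangenome fractions

From a genome × orthogroup count matrix (presence = count ≥ 1):

* **hard core** — OGs present in every genome;
* **soft core(k)** — OGs present in at least *k* genomes; `soft_core(n)`
  equals the hard core and the family is monotone in *k*. Thresholds
  are conventionally quoted as percentages of genomes, rounded half-up
  to two decimals (235 of 237 → 99.16%);
* **single-copy core** — OGs with exactly one gene in every genome (the
  input to concatenated marker phylogenies);
* **accumulation curves** — over random permutations of the genomes
  (default 300; without replacement, so curves terminate at the full
  collection), the running intersection (core), union (pangenome) and
  per-step union increment (new OGs, the sequential reading of
  "strain-specific"). The static reading — OGs present in exactly one
  genome — is available separately as `unique_to_one`. Summaries are
  per-k mean and quartiles; quartiles use the linear-interpolation
  convention. Per replicate, pan(k) = pan(k−1) + new(k) holds exactly.

Genomes assembled into more than 75 scaffolds (configurable) are
screened out before pangenome analysis, since heavily fragmented drafts
under-represent gene content.

## Richness rarefaction and extrapolation

Cluster sizes form an abundance vector **x** with total *n*, observed
richness *S_obs*, singletons *f₁* and doubletons *f₂*. Interpolation is
hypergeometric rarefaction, `S(m) = S_obs − Σᵢ C(n−xᵢ, m) / C(n, m)`,
computed with log-gamma functions for stability; S(n) = S_obs and
S(1) = 1. Unseen clusters are estimated by Chao1,
`f₀ = ((n−1)/n) f₁²/(2 f₂)`, with the bias-corrected form
`((n−1)/n) f₁(f₁−1)/(2(f₂+1))` when no doubletons exist. Extrapolation
is `S(n+m*) = S_obs + f₀ [1 − (1 − f₁/(n f₀ + f₁))^{m*}]`, continuous at
m = n and saturating at S_obs + f₀; with no singletons the curve is
flat at S_obs and a warning is emitted rather than an error.

Confidence bands are percentile bootstrap (default 1000 replicates,
95%): a bootstrap assemblage assigns each observed cluster probability
`Ĉ xᵢ/n` — where `Ĉ = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁ + 2f₂)` is the
estimated sample coverage — and splits the remaining mass equally over
⌈f₀⌉ hypothetical unseen clusters; each replicate draws *n* genomes
multinomially and recomputes the whole curve. The exact assemblage
construction is a design choice among several Chao-type variants; the
simple coverage-scaled version is used. This bootstrap is known to be
slightly biased low for interpolated points, so band endpoints are
widened where necessary to include the point estimate, keeping
ci_lo ≤ estimate ≤ ci_hi unconditionally. The band is Monte-Carlo noisy
at small replicate counts; its endpoint variance shrinks as replicates
grow (asserted in the tests).

## Trait profiling

For a group partition and a list of trait orthogroups, the profile cell
is the fraction of genomes in the group with the OG present (count ≥ 1),
so 1 means fixed in the group and 0 absent. Heatmap row and column
orderings come from average-linkage hierarchical clustering on Euclidean
distances (scipy), rows and columns independently; inputs are pre-sorted
lexicographically so ties resolve deterministically, and the ordering is
the dendrogram leaf order. Ortholog counts per genome sum the raw gene
counts over a family of OGs. Protein deduplication is literal:
case-insensitive exact string identity on residues, first-seen record
retained, with a multiplicity map preserving every original id.

## The synthetic-collection generator

The generator emulates the statistical structure the pipeline assumes,
not genome sequences. Genomes are nested in species nested in
phylogroups; each unordered genome pair draws one uniform distance from
a range chosen by relationship:

| relationship | default range |
|---|---|
| same species | 0.005 – 0.03 |
| same group, different species | 0.05 – 0.12 |
| different groups | 0.17 – 0.40 |

The ranges are strictly separated, so the species boundary 0.036 falls
in the species/group gap and group-level thresholds around 0.14 fall in
the group/between gap; recovery of the generating partitions by
thresholding is then exact, which is the basis of the recovery tests.
Distances are i.i.d. within range and symmetrized, with no metricity
enforced — real blast-based genome distances are not guaranteed metric,
and the clustering and NJ code must tolerate that.

Orthogroup content has three compartments: a hard core of OGs with one
gene in every genome (default 300); per-group shell OGs present in each
member genome with probability 0.7 (default 40 per group), absent
outside the group, each column forced to at least one presence so no OG
is empty; and per-genome cloud OGs unique to one genome, with a
Poisson(30) count per genome — near the average of ~33 new OGs per
added genome reported for large actinobacterial collections. Trait OGs
are shell-like columns restricted to a stated set of groups, so the
trait→group assignment is exactly recoverable from the profile.
Default collection shape is 10 groups × 2 species × 3 genomes
(60 genomes): large enough to exhibit the two-level structure, small
enough that the full threshold sweep and the exhaustive oracles run in
seconds.

One master seed feeds deterministic per-component child streams
(layout, distances, shell, cloud), so identical parameters give
byte-identical written collections.

What the generator does **not** emulate: sequence evolution, gene
gain/loss on a tree (cloud/shell content is exchangeable across genomes
within their compartment, with no phylogenetic signal), assembly
artifacts, or realistic alignment-fraction noise in distances. Passing
recovery tests therefore show the inference chain is correct under its
own assumptions — clean distance gaps, well-behaved orthogroup
compartments — not that real collections satisfy those assumptions;
on real data the sweep plateau may be narrow or absent, and fraction
curves inherit whatever biases the orthology inference introduced.

## Numerical and degenerate-input choices

* Distance matrices are symmetrized to `(D + Dᵀ)/2` after validation so
  later equality comparisons are exact; validation tolerance 1e-9.
* The sweep grid is built by integer index × step; endpoints inclusive.
* Adjusted Rand uses integer pair counts; division happens once.
* A single-genome matrix clusters to one singleton at any threshold.
* `percent_of_genomes` rounds half-up via `decimal`, not banker's
  rounding, matching how such thresholds are conventionally printed.
* Bootstrap, accumulation and simulation randomness all use
  `numpy.random.default_rng` seeded explicitly; no global state.
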