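# Methods

`ligomap` classifies a repertoire of E3 ubiquitin ligases (or any comparable
protein set) by combining distance measures from several data layers into a
single learned metric and parsing its Ward hierarchy into families. This
note documents the models, the defaults and their rationale, the synthetic
study conditions, numerical choices, and known limitations.

## Multi-scale distance measures

Twelve pairwise measures are computed, each scaled to [0, 1]:

| id | layer | definition |
|----|-------|------------|
| `LMS` | sequence | 1 − 2·LMS(P,Q)/(LMS(P,P)+LMS(Q,Q)); LMS sums, per overlapping 5-residue fragment of one protein, the best ungapped BLOSUM62 score against all fragments of the other, in both directions |
| `gamma` | sequence | a[(1−p)^(−1/a) − 1] with a = 2 and p the fraction of non-identical columns of the global alignment (BLOSUM62, affine gaps 10/0.5) |
| `Jac` | architecture | one minus the Jaccard index of the unique-domain sets |
| `GKgamma` | architecture | 1 − (1+γ)/2 with Goodman–Kruskal γ over same- vs reversed-ordered pairs of shared domains (first occurrences) |
| `Dup` | architecture | 1 − exp(−Σ\|ΔN_i\|/S) over per-domain repeat counts, S = Σ max(N_i) over the domain union |
| `Str` | structure | 1 − [TM(P,Q)+TM(Q,P)]/2 with the length-normalized TM-score under iterative superposition |
| `BP`/`CC`/`MF` | function | best-match-average Wang-method semantic distance per GO namespace |
| `ScL` | localization | cosine distance of compartment vectors (main weight 1.0, auxiliary 0.3) |
| `TE`/`ClE` | expression | 1 − (1+r_S)/2 with Spearman's rank correlation over tissue / cell-line profiles |

Design choices where a definition is genuinely open:

- **LMS symmetrization.** The fragment sum is taken in both directions
  (P→Q best matches plus Q→P best matches), which makes the measure
  symmetric and guarantees self-distance zero, since the normalization
  presumes LMS(P,Q) ≤ ½[LMS(P,P)+LMS(Q,Q)]. A positional (index-paired)
  fragment mode is deliberately not offered as the default because
  best-match is the only reading that is length-robust.
- **Gamma saturation.** An alignment with no identical column gives p = 1
  and an infinite distance; the +inf sentinel is mapped to 1 at scaling
  time, i.e. to the dataset maximum.
- **Repeat-count summation.** The duplication sum runs over the *union* of
  unique domains, each counted once; double-counting shared domains would
  double their contribution with no benefit.
- **Degenerate order comparison.** With fewer than two shared domains the
  Goodman–Kruskal γ is 0/0. Two identical single-domain architectures are
  assigned distance 0; anything else is an undefined pair.
- **Wang weights.** is_a edges contribute 0.8, part_of 0.6 (the method's
  conventional values); both are configurable on `OntologyGraph`. The
  best-match average uses GO_P in the second summation; a printed variant
  with GO_Q in both terms exists behind `printed_variant=True`.
- **TM-score.** d0(L) = 1.24·(L−15)^(1/3) − 1.8, clamped to 0.5 for
  L ≤ 21 so short toy segments stay defined (standard practice). The
  superposition seeds on all corresponding pairs and iteratively retains
  pairs with d_i < d0 (Kabsch via SVD) until the retained set repeats; the
  reported score is the maximum over iterations. The built-in mode pairs
  residues positionally over min(L_P, L_Q) — appropriate for the synthetic
  equal-length catalytic segments; real data should supply an external
  directed TM-score table (e.g. US-align output), which the `Str` measure
  consumes directly.
- **Undefined pairs.** A pair on which a measure is undefined (missing
  layer, degenerate input) is carried as NaN, and after min–max scaling is
  imputed to the median of the defined scaled entries; counts are recorded
  in the metadata sidecar. This keeps one incomplete protein from removing
  a whole row; strict callers can drop incomplete records up front.

## Metric learning

The emergent distance is D = Σ_i w_i d_i over the four components
`MF`, `gamma`, `Jac`, `Str` (domain composition, sequence, structure,
molecular function). Weights come from an exhaustive grid search
(default grid {0.05, 0.15, …, 0.95}): each weight vector is combined,
re-scaled to [0, 1] (weights need not sum to one, so fractional cutoffs
must be made comparable), Ward-clustered, cut at each fractional height h
in a grid mirroring the weight grid, and scored by element-centric
similarity (S_EC, α = 0.9) against partial class labels. Per h the 100
highest-scoring vectors are averaged (mean ± SD recorded; S_EC ties broken
by enumeration order); the stabilized weights are the mean of those per-h
means over the plateau region h ≥ 0.9 (configurable; 0.75 is the other
natural choice and both are exposed).

S_EC uses the hard-partition closed form: element i's affinity row places
α/|c(i)| on each member of its cluster plus 1−α on itself; per-element
agreement is 1 − (1/2α)·L1 between the two rows; the index is the mean.
This equals the graph-walk formulation of the cited index for hard
partitions and is 1 exactly when the partitions coincide.

Because S_EC depends only on the *direction* of the weight vector (the
combined matrix is re-scaled before tree building), distinct grid vectors
with proportional weights score identically; these structural ties are why
per-h weight means must be read as tendencies rather than point estimates.

## Hierarchy, cutting, bootstrap

Ward's minimum-variance linkage is applied directly to the (non-Euclidean)
distance matrix via SciPy's Lance–Williams update, without embedding
correction. `cut_fractional(tree, h)` removes merges above h·(maximum merge
height); h = 1 gives one cluster. Branch stability uses a leaf-resampling
bootstrap: each replicate draws n leaves with replacement, deduplicates,
rebuilds the tree on the induced sub-matrix, and a reference node counts as
present when its bipartition — restricted to the replicate's leaves, with
at least two leaves per side — occurs in the replicate tree; support is the
fraction of scorable replicates. A label-swapping resampling was considered
and rejected: permuting protein labels destroys all structure by
construction and cannot measure branch stability.

Families are numbered by decreasing size within their majority class
(RING1 is the largest RING-majority family); purity and class-level
outliers are reported per family, and trees round-trip through Newick with
supports as internal node labels.

## Downstream scores

- **Substrate categories.** A substrate with exactly one distinct E3 is
  E3-specific; with ≥ 2 E3s in one family, family-specific; spanning ≥ 2
  families, promiscuous. When a pair is reported by several evidence
  classes the strongest is kept (known > direct PPI > indirect PPI >
  predicted).
- **Essentiality.** Per guide NRC = log2(count·n·100/total + 1); per-guide
  LFC is endpoint NRC minus library NRC; gene LFC averages guides and
  replicates. p-values come from a two-sided one-sample t-test on
  replicate-level gene LFCs with Benjamini–Hochberg correction — an
  unmoderated approximation of an empirical-Bayes linear model; it needs at
  least three replicates for useful power (see below). Essential means
  |LFC| ≥ 1 and FDR ≤ 0.05.
- **Compound propensities.** LP_ij = log2[(n_ij/Σ_j n_ij)·(ΣΣ n/Σ_i n_ij)];
  zero cells are masked. pChEMBL = −log10(molar activity), so 1 µM ↦ 6.0;
  the activity filter flags pChEMBL ≥ 6.
- **Density peaks.** On a [0,1]²-normalized embedding, ρ_i counts neighbors
  within d_c (cutoff kernel; default d_c = 0.05, roughly the percent scale
  of the normalized space) and δ_i is the distance to the nearest
  higher-density point (the global peak takes the maximum pairwise
  distance). Centers satisfy ρ ≥ 20 and δ ≥ 0.1; all other points inherit
  the cluster of their nearest higher-density neighbor in a
  descending-density sweep, ties broken by index.

## Synthetic study conditions

The generator plants a three-class (RING/HECT/RBR-like), six-family,
ten-member structure across all layers: independent class ancestor
sequences, family ancestors at 0.6 substitution divergence from their
class ancestor, members at 0.35 from the family ancestor, 2% indel rate;
family domain vocabularies sharing a class catalytic domain and two
class-shared accessory domains whose order flips between families (so the
order measure sees both orientations), with one tandem-duplicated family
domain and 30% per-member architecture perturbation; 40-residue catalytic
segment traces jittered 1.0 Å per member around family templates spread
3.0 Å around class templates; GO terms drawn from family subtrees of a
balanced depth-4 ternary DAG (one part_of cross-edge per level) with a 50%
chance of one random extra term; family-specific compartments with 30%
auxiliary noise; and multiplicative log-normal expression noise (σ = 0.5)
around family profiles.

These divergence levels were chosen to mimic real protein families (tens
of percent sequence identity within a family, families within a class
related only distantly) and, importantly, to keep the weight-learning
objective *discriminating*: with near-identical within-family sequences
nearly every weight vector recovers the classes and the S_EC landscape
collapses into one large tie, which exercises nothing. The planted class
boundary sits high in the tree; `class_cut_h = 0.8` lies inside the
three-cluster window of the stabilized emergent tree across seeds by
construction of the two-level divergence hierarchy.

What the generator does **not** emulate: realistic family-size and length
distributions, phylogenetic (non-i.i.d.) substitution processes,
domain-boundary uncertainty, GO annotation depth bias, batch structure in
expression data, or structural divergence beyond isotropic jitter. Passing
tests therefore demonstrate correctness of the algorithms and their
end-to-end composition under controlled conditions, not performance on
real proteome-scale data.

The CRISPR fixture plants 20 dropout genes (endpoint counts ×0.25, i.e.
LFC −2) among 200 neutral genes, two guides per gene, Poisson counts at
mean 500, and **three** endpoint replicates. Three is the minimal realistic
design under the unmoderated t-test: with two replicates (df = 1) the
smallest attainable p-value at any realistic effect is ~0.015, above every
Benjamini–Hochberg cutoff at this scale, so no calls could ever be made;
moderated-variance models are what make two-replicate screens testable,
and those are outside this package's scope.

## Problem sizes and numerics

Default suites run at 30–60 proteins, a 5⁴-vector weight grid with five
cutoffs for learning experiments, 100 bootstrap replicates, 400-point
embeddings, and 220-gene guide tables — sizes at which every planted
property is stable across seeds while the whole pipeline remains
interactive. Matrix round trips are exact to 1e−12 (floats are written via
`repr`); Newick heights round-trip to 1e−9; tie-breaks are always by index
or enumeration order, so identical configuration and seed reproduce
byte-identical outputs end to end.

## Known limitations

- Ward on a non-Euclidean distance matrix is accepted as-is; heights are
  not guaranteed to correspond to any embedding.
- The built-in structural correspondence is positional; heterogeneous
  segment lengths need an external alignment (directed TM-score table).
- The grid search is exhaustive by design (10⁴ vectors at four measures);
  more measures require a coarser grid or pre-screening with
  `correlation_screen`.
- `density_peak_clusters` materializes the full O(n²) distance matrix;
  intended for embeddings up to a few tens of thousands of points.
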