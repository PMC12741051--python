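# ligomap

Multi-scale classification of E3 ubiquitin ligase repertoires: pairwise
protein distance measures across six data layers, weakly supervised linear
metric learning, hierarchical family classification with bootstrap support,
and the downstream scores used to annotate the resulting families.

## The problem

The human genome encodes hundreds of E3 ubiquitin ligases whose sequences,
domain architectures, 3D structures, functions, localizations, and
expression patterns are so heterogeneous that no single comparison — not
even a multiple sequence alignment — organizes them. `ligomap` addresses
this by computing twelve complementary pairwise distances
d<sup>i</sup><sub>PQ</sub> (sequence: local matching score and
alignment-based gamma; architecture: Jaccard, Goodman–Kruskal gamma,
duplication; structure: symmetrized TM-score; function: Wang-method GO
semantic distances per namespace; localization: weighted cosine;
expression: Spearman-based tissue and cell-line distances), each scaled to
[0, 1], and learning an **emergent distance**

&nbsp;&nbsp;&nbsp;&nbsp;D<sub>PQ</sub> = Σ<sub>i</sub> w<sub>i</sub> d<sup>i</sup><sub>PQ</sub>

whose weights maximize the element-centric clustering similarity
(S<sub>EC</sub>) between Ward-hierarchy clusters, cut at a fractional tree
height h, and partial class labels (RING/HECT/RBR) — a weakly supervised
grid search. The emergent tree is then cut into families, stabilized by a
leaf-resampling bootstrap, and annotated with curation and downstream
scores (cross-source consensus, catalytic-domain filtering,
complex/standalone mode, substrate-specificity categories, CRISPR
essentiality calls, compound-cluster propensities, density-peak clustering
of chemical embeddings).

A seeded synthetic generator plants a class/family structure across every
data layer, so the whole pipeline is testable without any downloads.

## Worked example

```python
from ligomap.synthetic import SyntheticConfig, generate_ligome
from ligomap.distances import EMERGENT_COMPONENTS, compute_all_distances
from ligomap.metric import learn_weights, combine, _rescaled_for_tree
from ligomap.tree import build_tree, cut_fractional, bootstrap_support
from ligomap.compare import element_centric_similarity

cfg = SyntheticConfig(seed=1)           # 3 classes, 6 families, 60 proteins
dataset, truth = generate_ligome(cfg)

matrices = list(compute_all_distances(dataset, measures=EMERGENT_COMPONENTS).values())
trajectory, weights = learn_weights(
    matrices, truth["class"],
    grid=(0.05, 0.25, 0.45, 0.65, 0.85),
    h_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
    top_k=100,
)
print({k: round(v, 3) for k, v in weights.as_dict().items()})
print("best S_EC:", trajectory.best_sec.max())

emergent = _rescaled_for_tree(combine(matrices, weights))
tree = build_tree(emergent)
classes = cut_fractional(tree, cfg.class_cut_h)
print("clusters:", classes.n_clusters,
      "S_EC vs planted classes:",
      round(element_centric_similarity(classes, truth["class"]), 3))
```

prints

```
{'MF': 0.1, 'gamma': 0.52, 'Jac': 0.29, 'Str': 0.522}
best S_EC: 1.0
clusters: 3 S_EC vs planted classes: 1.0
```

The stabilized weights say that, on this fixture, sequence (`gamma`) and
structure (`Str`) carry the most class-relevant signal; the emergent tree
cut at the planted fractional height recovers the three planted classes
exactly (S<sub>EC</sub> = 1), and cutting lower (h = 0.5) recovers the six
planted families. `ligomap.tree.bootstrap_support` attaches branch supports
(the planted family nodes reach 1.0 at 100 replicates).

The same pipeline is scriptable from the shell:

```sh
ligomap simulate --seed 5 --out fix/
ligomap distances --config fix/dataset.yaml --seed 5 --out dist/
ligomap learn --matrices dist/distance_MF.tsv --matrices dist/distance_gamma.tsv \
              --matrices dist/distance_Jac.tsv --matrices dist/distance_Str.tsv \
              --labels fix/truth_class.tsv --seed 5 --out learned/
ligomap tree  --matrices dist/distance_*.tsv --weights learned/stabilized_weights.json \
              --bootstrap 100 --seed 5 --out tree/
ligomap classify --matrix tree/emergent.tsv --labels fix/truth_class.tsv --h 0.5 \
              --seed 5 --out families/
```

Estimator-style entry points (`EmergentMetricLearner`,
`FamilyClassifier`, `DensityPeakClustering`) follow scikit-learn
conventions (`fit`/`transform`, `get_params`, trailing-underscore fitted
attributes) and compose with sklearn tooling.

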