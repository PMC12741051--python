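"""Seeded synthetic ligome fixtures with planted class/family structure.

The generator emulates every data layer the distance measures consume —
sequences descended from per-class and per-family ancestors, family-specific
domain architectures with tandem repeats, jittered catalytic-segment traces,
GO annotations drawn from family subtrees of a toy DAG, compartment
assignments, and expression profiles — plus toy downstream fixtures (ESI
networks, guide-count tables, compound embeddings). All randomness flows
from a single seed, so identical configs reproduce byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AMINO_ACIDS,
    DomainHit,
    LigomapError,
    LigomeDataset,
    OntologyGraph,
    Partition,
    ProteinRecord,
)
from .downstream import EsiNetwork


@dataclass
class SyntheticConfig:
    """Planted-structure generator settings.

    Defaults give 3 classes (RING/HECT/RBR-like) split into 6 families of 10
    members: within-family substitution rate 0.05, family-from-class
    divergence 0.3, independent class ancestors, 2% indel probability, and a
    0.5 A structural jitter on 40-residue catalytic segments.
    """

    class_names: tuple[str, ...] = ("RING", "HECT", "RBR")
    families_per_class: tuple[int, ...] = (3, 2, 1)
    family_size: int = 10
    ancestor_length: int = 240
    family_rate: float = 0.35  # member-from-family-ancestor substitution rate
    class_divergence: float = 0.6  # family-ancestor-from-class-ancestor rate
    indel_rate: float = 0.02
    segment_length: int = 40
    structure_sigma: float = 1.0  # member jitter, Angstrom
    family_structure_sigma: float = 3.0  # family template vs class template
    arch_perturb: float = 0.3
    n_go_terms: int = 4
    go_noise: float = 0.5
    go_branching: int = 3
    go_depth: int = 4
    n_compartments: int = 12
    loc_noise: float = 0.3
    tissue_dim: int = 40
    cellline_dim: int = 60
    expression_noise: float = 0.5
    n_sources: int = 8
    source_presence: float = 0.8
    class_cut_h: float = 0.8  # fractional cutoff at which classes are planted
    seed: int = 0

    def __post_init__(self):
        if self.family_size < 2:
            raise LigomapError("family size must be >= 2")
        if not 0.0 <= self.family_rate < 1.0 or not 0.0 <= self.class_divergence < 1.0:
            raise LigomapError("substitution rates must lie in [0, 1)")
        if self.structure_sigma < 0:
            raise LigomapError("structure jitter must be >= 0")
        if len(self.families_per_class) != len(self.class_names):
            raise LigomapError("families_per_class must match class_names")
        if max(self.families_per_class) > self.go_branching:
            raise LigomapError("family count per class exceeds the GO subtree fan-out")


def toy_ontology(
    branching: int = 3, depth: int = 4, namespaces: Sequence[str] = ("BP", "CC", "MF")
) -> OntologyGraph:
    """Balanced is_a tree of the given depth per namespace, plus one part_of
    cross-edge per level to exercise multi-parent propagation."""
    terms, edges = [], []
    for ns in namespaces:
        levels = [[f"{ns}:0"]]
        terms.append(f"{ns}:0")
        for lv in range(1, depth + 1):
            layer = []
            for parent in levels[-1]:
                for i in range(branching):
                    t = f"{parent}.{i}"
                    terms.append(t)
                    edges.append((t, parent, "is_a"))
                    layer.append(t)
            levels.append(layer)
        # one part_of cross-edge per level: first child of the last branch
        # also belongs to the first branch of the level above
        for lv in range(2, depth + 1):
            child = levels[lv][-branching]
            alt_parent = levels[lv - 1][0]
            if (child, alt_parent, "is_a") not in edges:
                edges.append((child, alt_parent, "part_of"))
    return OntologyGraph(terms, edges)


def _leaves_below(prefix: str, branching: int, extra_depth: int) -> list[str]:
    out = [prefix]
    for _ in range(extra_depth):
        out = [f"{t}.{i}" for t in out for i in range(branching)]
    return out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_sequence(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> str:
    """i.i.d. substitutions plus small insertions/deletions per site."""
    out = []
    aas = list(AMINO_ACIDS)
    for c in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(rng.choice(aas))  # insertion before the site
        if rng.random() < sub_rate:
            choices = [a for a in aas if a != c]
            out.append(rng.choice(choices))
        else:
            out.append(c)
    return "".join(out) if out else seq[:1]


def _random_chain(rng: np.random.Generator, n: int, step: float = 3.8) -> np.ndarray:
    steps = rng.normal(size=(n, 3))
    steps = step * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(steps, axis=0)


def generate_ligome(cfg: SyntheticConfig) -> tuple[LigomeDataset, dict[str, Partition]]:
    """Generate a planted-structure dataset plus class- and family-level truth."""
    rng = np.random.default_rng(cfg.seed)
    ontology = toy_ontology(cfg.go_branching, cfg.go_depth)
    compartments = [f"C{i:02d}" for i in range(cfg.n_compartments)]

    records = []
    class_truth: dict[str, str] = {}
    family_truth: dict[str, str] = {}
    fam_global = 0
    for ci, (cname, n_fam) in enumerate(zip(cfg.class_names, cfg.families_per_class)):
        class_ancestor = _random_sequence(rng, cfg.ancestor_length)
        class_template = _random_chain(rng, cfg.segment_length)
        class_expr_t = rng.uniform(1.0, 10.0, cfg.tissue_dim)
        class_expr_c = rng.uniform(1.0, 10.0, cfg.cellline_dim)
        for fi in range(n_fam):
            fam_name = f"{cname}-F{fi + 1}"
            ancestor = mutate_sequence(rng, class_ancestor, cfg.class_divergence, cfg.indel_rate)
            template = class_template + rng.normal(
                scale=cfg.family_structure_sigma or 1e-12, size=class_template.shape
            ) * (cfg.family_structure_sigma > 0)
            # family domain vocabulary: class catalytic domain + family domains,
            # one of which is tandem-duplicated
            cat = f"CAT_{cname}"
            fam_doms = [f"D{fam_global}{s}" for s in "abc"]
            # class-shared accessory domains appear in family-specific order so
            # the domain-order measure sees both same- and reversed-order pairs
            shared = [f"S_{cname}a", f"S_{cname}b"]
            if fi % 2:
                shared = shared[::-1]
            baseline = [cat] + shared + [fam_doms[0], fam_doms[1], fam_doms[1], fam_doms[2]]
            go_pools = {
                ns: _leaves_below(
                    f"{ns}:0.{ci}.{fi}", cfg.go_branching, cfg.go_depth - 2
                )
                for ns in ("BP", "CC", "MF")
            }
            all_leaves = {
                ns: _leaves_below(f"{ns}:0", cfg.go_branching, cfg.go_depth)
                for ns in ("BP", "CC", "MF")
            }
            main_comp = compartments[fam_global % cfg.n_compartments]
            aux_comp = compartments[(cfg.families_per_class[0] * 2 + ci) % cfg.n_compartments]
            fam_expr_t = class_expr_t + rng.uniform(0.0, 3.0, cfg.tissue_dim)
            fam_expr_c = class_expr_c + rng.uniform(0.0, 3.0, cfg.cellline_dim)
            for mi in range(cfg.family_size):
                pid = f"{cname}{fam_global}_{mi:02d}"
                seq = mutate_sequence(rng, ancestor, cfg.family_rate, cfg.indel_rate)
                doms = list(baseline)
                if rng.random() < cfg.arch_perturb and len(doms) > 2:
                    doms.pop(rng.integers(1, len(doms)))
                if rng.random() < cfg.arch_perturb:
                    doms.append(doms[rng.integers(0, len(doms))])
                arch, pos = [], 1
                for d in doms:
                    end = min(pos + 19, len(seq))
                    if end <= pos:
                        break
                    arch.append(DomainHit(d, pos, end))
                    pos = end + 6
                struct = template + rng.normal(
                    scale=cfg.structure_sigma, size=template.shape
                ) * (cfg.structure_sigma > 0)
                go_terms = {}
                for ns in ("BP", "CC", "MF"):
                    picks = set(
                        rng.choice(go_pools[ns], size=min(cfg.n_go_terms, len(go_pools[ns])), replace=False)
                    )
                    if rng.random() < cfg.go_noise:
                        picks.add(str(rng.choice(all_leaves[ns])))
                    go_terms[ns] = frozenset(picks)
                main = {main_comp}
                aux = {aux_comp}
                if rng.random() < cfg.loc_noise:
                    aux.add(str(rng.choice(compartments)))
                noise_t = np.exp(cfg.expression_noise * rng.normal(size=cfg.tissue_dim))
                noise_c = np.exp(cfg.expression_noise * rng.normal(size=cfg.cellline_dim))
                records.append(
                    ProteinRecord(
                        id=pid,
                        sequence=seq,
                        architecture=tuple(arch),
                        class_label=cname,
                        go_terms=go_terms,
                        localization_main=frozenset(main),
                        localization_aux=frozenset(aux),
                        expression_tissue=fam_expr_t * noise_t,
                        expression_cellline=fam_expr_c * noise_c,
                        structure=struct,
                    )
                )
                class_truth[pid] = cname
                family_truth[pid] = fam_name
            fam_global += 1

    ids = [r.id for r in records]
    membership = pd.DataFrame(
        rng.random((len(ids), cfg.n_sources)) < cfg.source_presence,
        index=ids,
        columns=[f"A{i + 1}" for i in range(cfg.n_sources)],
    ).astype(int)
    dataset = LigomeDataset(
        records=tuple(records),
        ontology=ontology,
        catalytic_domains=frozenset(f"CAT_{c}" for c in cfg.class_names),
        source_membership=membership,
    )
    truth = {"class": Partition(class_truth), "family": Partition(family_truth)}
    return dataset, truth


@dataclass
class DownstreamConfig:
    """Settings for the toy ESI network, guide-count table, and embedding."""

    n_substrates: int = 100
    proportions: tuple[float, float, float] = (0.2, 0.2, 0.6)  # e3/family/promiscuous
    n_neutral_genes: int = 200
    n_dropout_genes: int = 20
    guides_per_gene: int = 2
    depletion: float = 0.25
    n_replicates: int = 3
    mean_count: float = 500.0
    n_blobs: int = 2
    blob_size: int = 200
    blob_sigma: float = 0.03
    blob_separation: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise LigomapError("category proportions must sum to 1")


def generate_esi_network(
    family_map: dict[str, str], cfg: DownstreamConfig, rng: np.random.Generator
) -> tuple[EsiNetwork, dict[str, str]]:
    """ESI edges with planted specificity categories; returns (net, truth)."""
    e3s = sorted(family_map)
    by_family: dict[str, list[str]] = {}
    for e, f in family_map.items():
        by_family.setdefault(f, []).append(e)
    multi = [f for f, ms in by_family.items() if len(ms) >= 2]
    families = sorted(by_family)
    if len(families) < 2 or not multi:
        raise LigomapError("need >= 2 families and one multi-member family")
    n_e3 = int(round(cfg.proportions[0] * cfg.n_substrates))
    n_fam = int(round(cfg.proportions[1] * cfg.n_substrates))
    edges, truth = [], {}
    for s in range(cfg.n_substrates):
        sub = f"SUB{s:03d}"
        if s < n_e3:
            chosen = [rng.choice(e3s)]
            truth[sub] = "E3-specific"
        elif s < n_e3 + n_fam:
            fam = rng.choice(multi)
            chosen = list(rng.choice(sorted(by_family[fam]), size=2, replace=False))
            truth[sub] = "family-specific"
        else:
            f1, f2 = rng.choice(families, size=2, replace=False)
            chosen = [rng.choice(sorted(by_family[f1])), rng.choice(sorted(by_family[f2]))]
            if rng.random() < 0.5:
                chosen.append(rng.choice(e3s))
            truth[sub] = "promiscuous"
        for e3 in dict.fromkeys(chosen):
            ev = ["known", "direct_ppi", "indirect_ppi", "predicted"][rng.integers(0, 4)]
            edges.append((str(e3), sub, ev, float(rng.uniform(0.5, 1.0))))
    net = EsiNetwork(tuple(edges), dict(family_map))
    # re-derive truth categories from the edges actually drawn (a promiscuous
    # draw may collapse to fewer families when the same E3 is picked twice)
    from .downstream import categorize_substrates

    truth = categorize_substrates(net)
    return net, truth


def generate_guide_table(cfg: DownstreamConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    """Guide-count table with planted dropout genes; returns (table, planted ids)."""
    genes = [f"NEU{i:03d}" for i in range(cfg.n_neutral_genes)] + [
        f"DRP{i:03d}" for i in range(cfg.n_dropout_genes)
    ]
    planted = genes[cfg.n_neutral_genes :]
    rows = []
    for g in genes:
        factor = cfg.depletion if g.startswith("DRP") else 1.0
        for k in range(cfg.guides_per_gene):
            row = {
                "guide": f"{g}_g{k}",
                "gene": g,
                "library": int(rng.poisson(cfg.mean_count)),
            }
            for r in range(cfg.n_replicates):
                row[f"endpoint{r + 1}"] = int(rng.poisson(cfg.mean_count * factor))
            rows.append(row)
    return pd.DataFrame(rows), planted


def generate_embedding(cfg: DownstreamConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Planted dense blobs in [0, 1]^2; returns (points, blob labels)."""
    base = np.array([0.2, 0.5])
    centers = [base + np.array([i * cfg.blob_separation, 0.0]) for i in range(cfg.n_blobs)]
    pts, labels = [], []
    for k, c in enumerate(centers):
        pts.append(rng.normal(loc=c, scale=cfg.blob_sigma, size=(cfg.blob_size, 2)))
        labels.extend([k] * cfg.blob_size)
    return np.clip(np.vstack(pts), 0.0, 1.0), np.array(labels)


def generate_downstream_fixtures(
    family_map: dict[str, str],
    cfg: Optional[DownstreamConfig] = None,
) -> dict:
    """All downstream fixtures in one seeded bundle."""
    cfg = cfg or DownstreamConfig()
    rng = np.random.default_rng(cfg.seed)
    net, esi_truth = generate_esi_network(family_map, cfg, rng)
    guides, planted_genes = generate_guide_table(cfg, rng)
    points, blob_labels = generate_embedding(cfg, rng)
    return {
        "esi": net,
        "esi_truth": esi_truth,
        "guides": guides,
        "planted_genes": planted_genes,
        "points": points,
        "blob_labels": blob_labels,
    }
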