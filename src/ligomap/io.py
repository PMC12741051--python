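"""Readers and writers for every on-disk format, plus dataset loading.

Formats: FASTA sequences (via Biopython), TSV domain-architecture tables,
OBO ontology subsets (via obonet; only is_a and part_of are consumed), TSV
localization / expression / label / source-membership tables, whitespace
xyz traces for catalytic segments, square distance-matrix TSVs with a
one-line metadata header, and directed TM-score tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    GO_NAMESPACES,
    DistanceMatrix,
    DomainHit,
    LigomapError,
    LigomeDataset,
    OntologyGraph,
    ProteinRecord,
)

# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: DistanceMatrix, path) -> None:
    """Square TSV with label header row/column and a metadata comment line."""
    if not np.isfinite(matrix.values).all():
        raise LigomapError("refusing to write non-finite matrix")
    with open(path, "w") as fh:
        fh.write(f"# measure_id={matrix.measure_id}\tscaled={int(matrix.scaled)}\n")
        fh.write("\t".join(("id",) + matrix.labels) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            fh.write(lab + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        first = fh.readline()
        measure_id, scaled = "unnamed", False
        if first.startswith("#"):
            fields = dict(kv.split("=", 1) for kv in first[1:].strip().split("\t"))
            measure_id = fields.get("measure_id", measure_id)
            scaled = bool(int(fields.get("scaled", "0")))
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise LigomapError("matrix row labels do not match column labels")
    return DistanceMatrix(labels, df.to_numpy(dtype=float), measure_id, scaled)


def read_tm_table(path) -> dict[tuple[str, str], float]:
    """Directed TM-score table: columns idP, idQ, tm_pq, tm_qp."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        out[(str(row["idP"]), str(row["idQ"]))] = float(row["tm_pq"])
        out[(str(row["idQ"]), str(row["idP"]))] = float(row["tm_qp"])
    return out


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def write_obo(ontology: OntologyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: ligomap-toy\n\n")
        for term in sorted(ontology.terms):
            fh.write(f"[Term]\nid: {term}\nname: {term}\n")
            for parent, rel in ontology.parents(term):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


def read_obo(path, relation_weights=None) -> OntologyGraph:
    import obonet

    graph = obonet.read_obo(path)
    weights = dict(relation_weights or {"is_a": 0.8, "part_of": 0.6})
    edges = [
        (child, parent, rel)
        for child, parent, rel in graph.edges(keys=True)
        if rel in weights
    ]
    return OntologyGraph(graph.nodes, edges, weights)


# ---------------------------------------------------------------------------
# per-layer tables
# ---------------------------------------------------------------------------

def _read_architecture(path) -> dict[str, list[tuple[str, int, int]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list] = {}
    for i, row in df.iterrows():
        out.setdefault(str(row["protein_id"]), []).append(
            (str(row["domain_id"]), int(row["start"]), int(row["end"]), i)
        )
    return out


def _read_localization(path):
    df = pd.read_csv(path, sep="\t")
    main: dict[str, set] = {}
    aux: dict[str, set] = {}
    for _, row in df.iterrows():
        tier = str(row["tier"])
        if tier not in ("main", "aux"):
            raise LigomapError(f"unknown localization tier {tier!r}")
        target = main if tier == "main" else aux
        target.setdefault(str(row["protein_id"]), set()).add(str(row["compartment_id"]))
    return main, aux


def _read_structures(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep=r"\s+")
    return {
        str(pid): g[["x", "y", "z"]].to_numpy(dtype=float)
        for pid, g in df.groupby("protein_id", sort=False)
    }


def _read_go(path) -> dict[str, dict[str, set]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, set]] = {}
    for _, row in df.iterrows():
        ns = str(row["namespace"])
        if ns not in GO_NAMESPACES:
            raise LigomapError(f"unknown GO namespace {ns!r}")
        out.setdefault(str(row["protein_id"]), {n: set() for n in GO_NAMESPACES})[ns].add(
            str(row["term_id"])
        )
    return out


def load_dataset(config_path, strict: bool = False) -> LigomeDataset:
    """Load a cross-indexed dataset from a flat YAML config of layer paths.

    Recognized keys: ``fasta`` (required), ``architecture``, ``obo``, ``go``,
    ``localization``, ``expression_tissue``, ``expression_cellline``,
    ``structures``, ``labels``, ``sources``, ``catalytic_domains`` (list).
    Proteins missing a layer load with that layer absent; GO terms missing
    from the ontology warn and drop (or raise under ``strict``).
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def p(key) -> Optional[Path]:
        if key not in cfg or cfg[key] is None:
            return None
        path = Path(cfg[key])
        return path if path.is_absolute() else base / path

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(p("fasta")), "fasta"):
        if rec.id in seqs:
            raise LigomapError(f"duplicate protein id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq)

    arch = _read_architecture(p("architecture")) if p("architecture") else {}
    ontology = read_obo(p("obo")) if p("obo") else None
    go = _read_go(p("go")) if p("go") else {}
    loc_main, loc_aux = _read_localization(p("localization")) if p("localization") else ({}, {})
    expr_t = pd.read_csv(p("expression_tissue"), sep="\t", index_col=0) if p("expression_tissue") else None
    expr_c = pd.read_csv(p("expression_cellline"), sep="\t", index_col=0) if p("expression_cellline") else None
    structures = _read_structures(p("structures")) if p("structures") else {}
    labels = (
        pd.read_csv(p("labels"), sep="\t", index_col=0).iloc[:, 0].astype(str).to_dict()
        if p("labels")
        else {}
    )
    sources = pd.read_csv(p("sources"), sep="\t", index_col=0) if p("sources") else None

    records = []
    for pid, seq in seqs.items():
        hits = []
        for domain_id, start, end, rownum in arch.get(pid, []):
            if end > len(seq) or start < 1:
                raise LigomapError(
                    f"architecture row {rownum}: interval [{start}, {end}] for "
                    f"{pid} outside sequence of length {len(seq)}"
                )
            hits.append(DomainHit(domain_id, start, end))
        terms = {ns: set(v) for ns, v in go.get(pid, {}).items()}
        if ontology is not None:
            for ns in list(terms):
                missing = terms[ns] - ontology.terms
                if missing:
                    if strict:
                        raise LigomapError(
                            f"{pid}: GO terms absent from ontology: {sorted(missing)}"
                        )
                    warnings.warn(
                        f"{pid}: dropping GO terms absent from ontology: {sorted(missing)}",
                        stacklevel=2,
                    )
                    terms[ns] -= missing
        records.append(
            ProteinRecord(
                id=pid,
                sequence=seq,
                architecture=tuple(hits),
                class_label=labels.get(pid),
                go_terms={ns: frozenset(terms.get(ns, ())) for ns in GO_NAMESPACES},
                localization_main=frozenset(loc_main.get(pid, ())),
                localization_aux=frozenset(loc_aux.get(pid, ())),
                expression_tissue=expr_t.loc[pid].to_numpy() if expr_t is not None and pid in expr_t.index else None,
                expression_cellline=expr_c.loc[pid].to_numpy() if expr_c is not None and pid in expr_c.index else None,
                structure=structures.get(pid),
            )
        )
    return LigomeDataset(
        records=tuple(records),
        ontology=ontology,
        catalytic_domains=frozenset(cfg.get("catalytic_domains", ())),
        source_membership=sources,
    )


def write_dataset(dataset: LigomeDataset, out_dir) -> Path:
    """Write every layer of a dataset as the fixture bundle load_dataset reads.

    Returns the path of the written YAML config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset.records],
        str(out / "sequences.fasta"),
        "fasta",
    )
    arch_rows = [
        {"protein_id": r.id, "domain_id": h.domain_id, "start": h.start, "end": h.end}
        for r in dataset.records
        for h in r.architecture
    ]
    pd.DataFrame(arch_rows).to_csv(out / "architecture.tsv", sep="\t", index=False)
    go_rows = [
        {"protein_id": r.id, "namespace": ns, "term_id": t}
        for r in dataset.records
        for ns in GO_NAMESPACES
        for t in sorted(r.go_terms[ns])
    ]
    pd.DataFrame(go_rows).to_csv(out / "go.tsv", sep="\t", index=False)
    loc_rows = [
        {"protein_id": r.id, "compartment_id": c, "tier": tier}
        for r in dataset.records
        for tier, comps in (("main", sorted(r.localization_main)), ("aux", sorted(r.localization_aux)))
        for c in comps
    ]
    pd.DataFrame(loc_rows).to_csv(out / "localization.tsv", sep="\t", index=False)
    for attr, fname in (
        ("expression_tissue", "expression_tissue.tsv"),
        ("expression_cellline", "expression_cellline.tsv"),
    ):
        rows = {r.id: getattr(r, attr) for r in dataset.records if getattr(r, attr) is not None}
        if rows:
            pd.DataFrame.from_dict(rows, orient="index").to_csv(out / fname, sep="\t")
    struct_rows = [
        {"protein_id": r.id, "x": repr(float(x)), "y": repr(float(y)), "z": repr(float(z))}
        for r in dataset.records
        if r.structure is not None
        for x, y, z in r.structure
    ]
    if struct_rows:
        pd.DataFrame(struct_rows).to_csv(out / "structures.tsv", sep="\t", index=False)
    labels = {r.id: r.class_label for r in dataset.records if r.class_label}
    if labels:
        pd.Series(labels, name="class_label").rename_axis("protein_id").to_csv(
            out / "labels.tsv", sep="\t"
        )
    if dataset.ontology is not None:
        write_obo(dataset.ontology, out / "ontology.obo")
    if dataset.source_membership is not None:
        dataset.source_membership.to_csv(out / "sources.tsv", sep="\t")
    cfg = {
        "fasta": "sequences.fasta",
        "architecture": "architecture.tsv",
        "go": "go.tsv",
        "localization": "localization.tsv",
        "catalytic_domains": sorted(dataset.catalytic_domains),
    }
    if dataset.ontology is not None:
        cfg["obo"] = "ontology.obo"
    if (out / "expression_tissue.tsv").exists():
        cfg["expression_tissue"] = "expression_tissue.tsv"
    if (out / "expression_cellline.tsv").exists():
        cfg["expression_cellline"] = "expression_cellline.tsv"
    if struct_rows:
        cfg["structures"] = "structures.tsv"
    if labels:
        cfg["labels"] = "labels.tsv"
    if dataset.source_membership is not None:
        cfg["sources"] = "sources.tsv"
    config_path = out / "dataset.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config_path


def read_partition(path):
    from .datatypes import Partition

    df = pd.read_csv(path, sep="\t")
    return Partition(
        {str(r["element_id"]): str(r["cluster_id"]) for _, r in df.iterrows()}
    )


def write_partition(partition, path) -> None:
    rows = [
        {"element_id": e, "cluster_id": partition.assignment[e]}
        for e in partition.elements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
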