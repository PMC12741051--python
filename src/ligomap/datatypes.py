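"""Core data model shared by every ligomap module.

The central objects are :class:`ProteinRecord` (one protein's multi-layer
description), :class:`LigomeDataset` (a cross-indexed collection of records
plus an ontology and catalytic-domain set), :class:`DistanceMatrix` (a
labeled symmetric pairwise distance matrix for one measure), and
:class:`Partition` / :class:`ClusterTree` for clustering results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

GO_NAMESPACES = ("BP", "CC", "MF")


class LigomapError(ValueError):
    """Base class for validation errors raised by ligomap."""


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation: 1-based inclusive coordinates on the sequence."""

    domain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise LigomapError(
                f"invalid domain interval [{self.start}, {self.end}] for {self.domain_id}"
            )


def _sort_architecture(hits: Sequence[DomainHit]) -> tuple[DomainHit, ...]:
    # order by start, ties by end then domain id (InterPro-style convention)
    return tuple(sorted(hits, key=lambda h: (h.start, h.end, h.domain_id)))


@dataclass
class ProteinRecord:
    """One protein across all data layers; absent layers are ``None``/empty."""

    id: str
    sequence: str
    architecture: tuple[DomainHit, ...] = ()
    class_label: Optional[str] = None
    go_terms: Mapping[str, frozenset] = field(
        default_factory=lambda: {ns: frozenset() for ns in GO_NAMESPACES}
    )
    localization_main: frozenset = frozenset()
    localization_aux: frozenset = frozenset()
    expression_tissue: Optional[np.ndarray] = None
    expression_cellline: Optional[np.ndarray] = None
    structure: Optional[np.ndarray] = None  # (L, 3) catalytic-segment trace

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise LigomapError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise LigomapError(f"{self.id}: non-standard residues {sorted(bad)}")
        self.architecture = _sort_architecture(self.architecture)
        for h in self.architecture:
            if h.end > len(self.sequence):
                raise LigomapError(
                    f"{self.id}: domain {h.domain_id} interval "
                    f"[{h.start}, {h.end}] exceeds sequence length {len(self.sequence)}"
                )
        self.go_terms = {ns: frozenset(self.go_terms.get(ns, ())) for ns in GO_NAMESPACES}
        for attr in ("expression_tissue", "expression_cellline"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if (v < 0).any():
                    raise LigomapError(f"{self.id}: negative {attr} values")
                setattr(self, attr, v)
        if self.structure is not None:
            s = np.asarray(self.structure, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3:
                raise LigomapError(f"{self.id}: structure must be an (L, 3) array")
            self.structure = s
        self.localization_main = frozenset(self.localization_main)
        self.localization_aux = frozenset(self.localization_aux)

    @property
    def domain_ids(self) -> tuple[str, ...]:
        """Domain identifiers in N->C order (repeats kept)."""
        return tuple(h.domain_id for h in self.architecture)

    @property
    def unique_domains(self) -> frozenset:
        return frozenset(self.domain_ids)


class OntologyGraph:
    """Acyclic child->parent term graph with per-relation contribution weights.

    Parameters
    ----------
    terms : iterable of str
    edges : iterable of (child, parent, relation)
    relation_weights : mapping relation -> weight in (0, 1)
    """

    def __init__(self, terms, edges, relation_weights=None):
        self.terms = frozenset(terms)
        self.relation_weights = dict(relation_weights or {"is_a": 0.8, "part_of": 0.6})
        for rel, w in self.relation_weights.items():
            if not 0.0 < w < 1.0:
                raise LigomapError(f"relation weight for {rel!r} must be in (0, 1)")
        self._parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, parent, rel in edges:
            if child not in self.terms or parent not in self.terms:
                raise LigomapError(f"edge ({child}, {parent}) references unknown term")
            if rel not in self.relation_weights:
                raise LigomapError(f"unknown relation {rel!r}")
            self._parents[child].append((parent, rel))
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict[str, int] = {}

        def visit(t):
            state[t] = 1
            for p, _ in self._parents[t]:
                s = state.get(p)
                if s == 1:
                    raise LigomapError("ontology graph contains a cycle")
                if s is None:
                    visit(p)
            state[t] = 2

        for t in self.terms:
            if t not in state:
                visit(t)

    def parents(self, term: str) -> list[tuple[str, str]]:
        return self._parents[term]

    def ancestor_dag(self, term: str) -> dict[str, list[tuple[str, float]]]:
        """DAG of ``term`` plus all its ancestors.

        Returns a mapping ``t -> [(child_in_dag, edge_weight), ...]`` giving,
        for every node of the DAG, the DAG-internal children through which a
        semantic contribution can propagate up from ``term``.
        """
        if term not in self.terms:
            raise LigomapError(f"unknown term {term!r}")
        nodes = {term}
        stack = [term]
        children: dict[str, list[tuple[str, float]]] = {term: []}
        while stack:
            t = stack.pop()
            for p, rel in self._parents[t]:
                children.setdefault(p, []).append((t, self.relation_weights[rel]))
                if p not in nodes:
                    nodes.add(p)
                    stack.append(p)
        return children


@dataclass
class SubstitutionMatrix:
    """Symmetric residue substitution scores over a fixed alphabet."""

    alphabet: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise LigomapError("substitution matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise LigomapError("substitution matrix must be symmetric")
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    def encode(self, sequence: str) -> np.ndarray:
        try:
            return np.fromiter(
                (self._index[c] for c in sequence), dtype=np.intp, count=len(sequence)
            )
        except KeyError as e:  # pragma: no cover - guarded by ProteinRecord
            raise LigomapError(f"unscoreable residue {e.args[0]!r}")

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """BLOSUM62 over the 20 standard residues plus X (X scores -1 vs all)."""
        from Bio.Align import substitution_matrices

        b = substitution_matrices.load("BLOSUM62")
        alphabet = AMINO_ACIDS + "X"
        n = len(alphabet)
        scores = np.full((n, n), -1.0)
        for i, a in enumerate(AMINO_ACIDS):
            for j, c in enumerate(AMINO_ACIDS):
                scores[i, j] = b[a][c]
        return cls(alphabet, scores)


@dataclass
class DistanceMatrix:
    """Labeled symmetric pairwise distances for one measure.

    Undefined pairs are carried as NaN and +inf sentinels until
    :func:`ligomap.distances.scale_unit_interval` resolves them; a matrix with
    ``scaled=True`` must be finite and within [0, 1].
    """

    labels: tuple[str, ...]
    values: np.ndarray
    measure_id: str = "unnamed"
    scaled: bool = False

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if len(self.labels) == 0:
            raise LigomapError("empty label list")
        if len(set(self.labels)) != len(self.labels):
            raise LigomapError("duplicate labels")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise LigomapError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            eq = (v == v.T) | (np.isnan(v) & np.isnan(v.T))
        if not eq.all():
            raise LigomapError("matrix is not symmetric")
        if np.diagonal(v).any():
            raise LigomapError("diagonal must be zero")
        if self.scaled:
            if not np.isfinite(v).all():
                raise LigomapError("scaled matrix must be finite")
            if v.min() < 0 or v.max() > 1:
                raise LigomapError("scaled matrix entries must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values, checks=False)

    def reindex(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            tuple(labels), self.values[np.ix_(idx, idx)], self.measure_id, self.scaled
        )


class Partition:
    """Hard assignment of elements to clusters."""

    def __init__(self, assignment: Mapping[str, object]):
        if not assignment:
            raise LigomapError("empty partition")
        self.assignment = dict(assignment)
        self.elements = tuple(sorted(self.assignment))

    @classmethod
    def from_labels(cls, elements: Iterable[str], labels: Iterable[object]) -> "Partition":
        return cls(dict(zip(elements, labels, strict=True)))

    def clusters(self) -> dict[object, frozenset]:
        out: dict[object, set] = {}
        for e, c in self.assignment.items():
            out.setdefault(c, set()).add(e)
        return {c: frozenset(m) for c, m in out.items()}

    def labels_for(self, elements: Sequence[str]) -> list:
        return [self.assignment[e] for e in elements]

    def __eq__(self, other):
        if not isinstance(other, Partition):
            return NotImplemented
        return set(self.clusters().values()) == set(other.clusters().values())

    def __len__(self):
        return len(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class ClusterTree:
    """Binary merge tree: SciPy-style linkage plus leaf labels and supports."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # (n-1, 4): child, child, height, size
    supports: Optional[np.ndarray] = None  # per internal node, merge order

    def __post_init__(self):
        self.labels = tuple(self.labels)
        z = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if z.shape != (n - 1, 4):
            raise LigomapError("linkage shape must be (n-1, 4)")
        if (np.diff(z[:, 2]) < -1e-9).any():
            raise LigomapError("merge heights must be non-decreasing")
        self.linkage = z
        if self.supports is not None:
            s = np.asarray(self.supports, dtype=float)
            if s.shape != (n - 1,) or s.min() < 0 or s.max() > 1:
                raise LigomapError("supports must be n-1 values in [0, 1]")
            self.supports = s

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leafsets(self) -> list[frozenset]:
        """Leaf-label set under each internal node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset] = [frozenset([l]) for l in self.labels]
        out = []
        for a, b, _, _ in self.linkage:
            s = sets[int(a)] | sets[int(b)]
            sets.append(s)
            out.append(s)
        return out

    def max_height(self) -> float:
        return float(self.linkage[-1, 2])


@dataclass
class LigomeDataset:
    """Cross-indexed multi-layer dataset plus ontology and catalytic domains."""

    records: tuple[ProteinRecord, ...]
    ontology: Optional[OntologyGraph] = None
    catalytic_domains: frozenset = frozenset()
    source_membership: Optional["object"] = None  # pandas DataFrame: protein x source

    def __post_init__(self):
        self.records = tuple(self.records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LigomapError(f"duplicate protein ids: {dup}")
        self._by_id = {r.id: r for r in self.records}
        if self.ontology is not None:
            for r in self.records:
                for ns in GO_NAMESPACES:
                    missing = r.go_terms[ns] - self.ontology.terms
                    if missing:
                        raise LigomapError(
                            f"{r.id}: GO terms absent from ontology: {sorted(missing)}"
                        )

    def __getitem__(self, pid: str) -> ProteinRecord:
        return self._by_id[pid]

    def __len__(self):
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def missing_layers(self) -> dict[str, list[str]]:
        """Map protein id -> names of absent layers."""
        out = {}
        for r in self.records:
            absent = []
            if r.structure is None:
                absent.append("structure")
            if not r.architecture:
                absent.append("architecture")
            if not any(r.go_terms[ns] for ns in GO_NAMESPACES):
                absent.append("go")
            if not (r.localization_main or r.localization_aux):
                absent.append("localization")
            if r.expression_tissue is None:
                absent.append("expression_tissue")
            if r.expression_cellline is None:
                absent.append("expression_cellline")
            if absent:
                out[r.id] = absent
        return out

    def class_partition(self) -> Partition:
        labeled = {r.id: r.class_label for r in self.records if r.class_label}
        if not labeled:
            raise LigomapError("no class labels present")
        return Partition(labeled)
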