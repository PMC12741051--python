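"""The twelve pairwise protein distance measures and their unit scaling.

Measures span six granularity layers:

* sequence: local matching score (``LMS``) and global-alignment gamma
  (``gamma``) distances;
* domain architecture: Jaccard (``Jac``), Goodman-Kruskal gamma
  (``GKgamma``), and duplication (``Dup``) distances;
* 3D structure: symmetrized TM-score distance (``Str``);
* function: Wang-method semantic distances per GO namespace
  (``BP``/``CC``/``MF``);
* subcellular localization: weighted cosine distance (``ScL``);
* expression: Spearman-based tissue (``TE``) and cell-line (``ClE``)
  co-expression distances.

Pairs on which a measure is undefined (missing layer, degenerate input) are
carried as NaN; saturated gamma distances as +inf. Both are resolved by
:func:`scale_unit_interval`, which min-max scales each matrix to [0, 1] and
imputes undefined pairs to the median of defined scaled entries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .datatypes import (
    DistanceMatrix,
    LigomapError,
    LigomeDataset,
    OntologyGraph,
    ProteinRecord,
    SubstitutionMatrix,
)

MEASURE_IDS = (
    "LMS", "gamma", "Jac", "GKgamma", "Dup", "Str",
    "BP", "CC", "MF", "ScL", "TE", "ClE",
)

#: the four measures combined into the emergent metric
EMERGENT_COMPONENTS = ("MF", "gamma", "Jac", "Str")


# ---------------------------------------------------------------------------
# sequence layer
# ---------------------------------------------------------------------------

def _fragment_scores(p: np.ndarray, q: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Matrix of ungapped k-fragment scores: F[i, j] = score(P[i:i+k], Q[j:j+k])."""
    s = scores[p[:, None], q[None, :]]
    np_, nq = len(p) - k + 1, len(q) - k + 1
    f = np.zeros((np_, nq))
    for t in range(k):
        f += s[t : t + np_, t : t + nq]
    return f


def _lms(p: np.ndarray, q: np.ndarray, scores: np.ndarray, k: int) -> float:
    """Both-direction best-fragment local matching score."""
    f = _fragment_scores(p, q, scores, k)
    return float(f.max(axis=1).sum() + f.max(axis=0).sum())


def lms_distance(
    P: ProteinRecord,
    Q: ProteinRecord,
    subst: Optional[SubstitutionMatrix] = None,
    k: int = 5,
) -> float:
    """Alignment-free local-matching-score distance.

    ``1 - 2 LMS(P,Q) / (LMS(P,P) + LMS(Q,Q))`` where ``LMS`` sums, for every
    overlapping k-residue fragment of one protein, the best ungapped BLOSUM62
    score against all fragments of the other (both directions).
    """
    subst = subst or SubstitutionMatrix.blosum62()
    if len(P.sequence) < k or len(Q.sequence) < k:
        raise LigomapError(f"sequences must be at least {k} residues for LMS")
    p, q = subst.encode(P.sequence), subst.encode(Q.sequence)
    self_p = _lms(p, p, subst.scores, k)
    self_q = _lms(q, q, subst.scores, k)
    if self_p <= 0 or self_q <= 0:
        raise LigomapError("non-positive LMS self-score (degenerate sequence)")
    return 1.0 - 2.0 * _lms(p, q, subst.scores, k) / (self_p + self_q)


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment and its difference fraction ``p``."""

    aligned_p: str
    aligned_q: str

    def __post_init__(self):
        if len(self.aligned_p) != len(self.aligned_q):
            raise LigomapError("gapped strings must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_p)

    @property
    def n_diff(self) -> int:
        """Columns with a substitution or an indel."""
        return sum(a != b for a, b in zip(self.aligned_p, self.aligned_q))

    @property
    def p(self) -> float:
        return self.n_diff / self.length


def _make_aligner(subst: SubstitutionMatrix, gap_open: float, gap_extend: float):
    from Bio.Align import PairwiseAligner, substitution_matrices

    m = substitution_matrices.Array(alphabet=subst.alphabet, dims=2)
    for i, a in enumerate(subst.alphabet):
        for j, b in enumerate(subst.alphabet):
            m[a, b] = subst.scores[i, j]
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_alignment(
    P: ProteinRecord,
    Q: ProteinRecord,
    subst: Optional[SubstitutionMatrix] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    _aligner=None,
) -> AlignmentResult:
    """Needleman-Wunsch global alignment (affine gaps, BLOSUM62 default)."""
    aligner = _aligner or _make_aligner(subst or SubstitutionMatrix.blosum62(), gap_open, gap_extend)
    aln = aligner.align(P.sequence, Q.sequence)[0]
    return AlignmentResult(str(aln[0]), str(aln[1]))


def gamma_from_p(p: float, a: float = 2.0) -> float:
    """Evolutionary gamma distance ``a[(1-p)^(-1/a) - 1]``; +inf at p = 1."""
    if not 0.0 <= p <= 1.0:
        raise LigomapError("p must lie in [0, 1]")
    if p == 1.0:
        return np.inf
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


def gamma_distance(
    P: ProteinRecord,
    Q: ProteinRecord,
    subst: Optional[SubstitutionMatrix] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    a: float = 2.0,
    _aligner=None,
) -> float:
    """Gamma distance from the non-identical-column fraction of the global alignment."""
    if a <= 0:
        raise LigomapError("a must be positive")
    aln = global_alignment(P, Q, subst, gap_open, gap_extend, _aligner=_aligner)
    return gamma_from_p(aln.p, a)


# ---------------------------------------------------------------------------
# domain-architecture layer
# ---------------------------------------------------------------------------

def jaccard_distance(P: ProteinRecord, Q: ProteinRecord) -> float:
    """One minus the Jaccard index of the unique domain sets."""
    a, b = P.unique_domains, Q.unique_domains
    if not a and not b:
        return np.nan
    inter = len(a & b)
    return 1.0 - inter / (len(a) + len(b) - inter)


def gk_gamma_distance(P: ProteinRecord, Q: ProteinRecord) -> float:
    """Goodman-Kruskal gamma distance on the order of shared domains.

    Positions are first occurrences; gamma compares all unordered pairs of
    distinct shared domains for same vs reversed ordering.
    """
    pos_p = {}
    for i, d in enumerate(P.domain_ids):
        pos_p.setdefault(d, i)
    pos_q = {}
    for i, d in enumerate(Q.domain_ids):
        pos_q.setdefault(d, i)
    shared = sorted(set(pos_p) & set(pos_q))
    n_same = n_rev = 0
    for d1, d2 in itertools.combinations(shared, 2):
        sp = np.sign(pos_p[d1] - pos_p[d2])
        sq = np.sign(pos_q[d1] - pos_q[d2])
        if sp == sq:
            n_same += 1
        else:
            n_rev += 1
    if n_same + n_rev == 0:
        if len(shared) == 1 and P.unique_domains == Q.unique_domains:
            return 0.0
        return np.nan
    gamma = (n_same - n_rev) / (n_same + n_rev)
    return 1.0 - (1.0 + gamma) / 2.0


def duplication_distance(P: ProteinRecord, Q: ProteinRecord) -> float:
    """Tandem-repeat overlap distance ``1 - exp(-sum|dN_i|/S)`` over the domain union."""
    if not P.domain_ids and not Q.domain_ids:
        return np.nan
    from collections import Counter

    cp, cq = Counter(P.domain_ids), Counter(Q.domain_ids)
    union = set(cp) | set(cq)
    s = sum(max(cp[d], cq[d]) for d in union)
    diff = sum(abs(cp[d] - cq[d]) for d in union)
    return 1.0 - float(np.exp(-diff / s))


# ---------------------------------------------------------------------------
# structure layer
# ---------------------------------------------------------------------------

def tm_d0(l_ref: int) -> float:
    """Length-dependent TM-score normalization; floored at 0.5 for short segments."""
    if l_ref <= 21:
        return 0.5
    return 1.24 * (l_ref - 15.0) ** (1.0 / 3.0) - 1.8


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||p - (q @ R.T + t)||."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, pc - qc @ r.T


def tm_score(
    p_struct: np.ndarray,
    q_struct: np.ndarray,
    correspondence: Optional[Sequence[tuple[int, int]]] = None,
    l_ref: Optional[int] = None,
    max_iter: int = 50,
) -> float:
    """TM-score of Q against reference P under iterative superposition.

    Seeds the superposition on all corresponding pairs, then iteratively
    retains pairs with ``d_i < d0`` and re-superposes until the retained set
    stabilizes; returns the maximum score over iterations. Normalized by the
    reference length ``l_ref`` (default: number of residues of P), hence
    asymmetric.
    """
    p = np.asarray(p_struct, dtype=float)
    q = np.asarray(q_struct, dtype=float)
    if correspondence is None:
        m = min(len(p), len(q))
        correspondence = [(i, i) for i in range(m)]
    pairs = np.asarray(list(correspondence), dtype=int)
    if len(pairs) < 3:
        raise LigomapError("need at least 3 corresponding pairs to superpose")
    l_ref = int(l_ref if l_ref is not None else len(p))
    d0 = tm_d0(l_ref)
    pa, qa = p[pairs[:, 0]], q[pairs[:, 1]]

    retained = np.ones(len(pairs), dtype=bool)
    best = 0.0
    seen = set()
    for _ in range(max_iter):
        r, t = _kabsch(pa[retained], qa[retained])
        d = np.linalg.norm(pa - (qa @ r.T + t), axis=1)
        best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref))
        new = d < d0
        if new.sum() < 3:
            break
        key = new.tobytes()
        if key in seen:
            break
        seen.add(key)
        retained = new
    return best


def structural_distance(
    P: ProteinRecord,
    Q: ProteinRecord,
    tm_table: Optional[dict] = None,
) -> float:
    """Symmetrized structural distance ``1 - [TM(P,Q) + TM(Q,P)]/2``.

    ``tm_table`` maps (id_a, id_b) -> directed TM-score (e.g. parsed from a
    US-align output table) and takes precedence over built-in superposition.
    """
    if tm_table is not None:
        try:
            t_pq = tm_table[(P.id, Q.id)]
            t_qp = tm_table[(Q.id, P.id)]
        except KeyError:
            return np.nan
        return 1.0 - (t_pq + t_qp) / 2.0
    if P.structure is None or Q.structure is None:
        return np.nan
    t_pq = tm_score(P.structure, Q.structure)
    t_qp = tm_score(Q.structure, P.structure)
    return 1.0 - (t_pq + t_qp) / 2.0


# ---------------------------------------------------------------------------
# function layer (Wang-method semantic similarity)
# ---------------------------------------------------------------------------

def _s_values(term: str, ontology: OntologyGraph) -> dict[str, float]:
    """Semantic contribution S_term(t) for every t in the ancestor DAG of term."""
    children = ontology.ancestor_dag(term)
    memo: dict[str, float] = {term: 1.0}

    def s(t: str) -> float:
        if t in memo:
            return memo[t]
        memo[t] = max(w * s(c) for c, w in children[t])
        return memo[t]

    for t in children:
        s(t)
    return memo


def term_similarity(x: str, y: str, ontology: OntologyGraph) -> float:
    """Wang semantic similarity between two ontology terms."""
    sx, sy = _s_values(x, ontology), _s_values(y, ontology)
    common = set(sx) & set(sy)
    denom = sum(sx.values()) + sum(sy.values())
    return sum(sx[t] + sy[t] for t in common) / denom


def semantic_distance(
    P: ProteinRecord,
    Q: ProteinRecord,
    namespace: str,
    ontology: OntologyGraph,
    printed_variant: bool = False,
    _sim=None,
) -> float:
    """Best-match-average semantic distance between two GO term sets.

    ``printed_variant=True`` reproduces a variant in which the second
    summation is also taken against GO_Q rather than GO_P.
    """
    gp, gq = sorted(P.go_terms[namespace]), sorted(Q.go_terms[namespace])
    if not gp or not gq:
        return np.nan
    sim = _sim or (lambda a, b: term_similarity(a, b, ontology))
    total = sum(max(sim(x, y) for y in gq) for x in gp)
    second = gq if printed_variant else gp
    total += sum(max(sim(x, y) for y in second) for x in gq)
    return 1.0 - total / (len(gp) + len(gq))


# ---------------------------------------------------------------------------
# localization and expression layers
# ---------------------------------------------------------------------------

def _loc_vector(rec: ProteinRecord, universe: Sequence[str], main_w: float, aux_w: float):
    v = np.zeros(len(universe))
    for i, c in enumerate(universe):
        if c in rec.localization_main:
            v[i] = main_w  # main weight wins if annotated in both tiers
        elif c in rec.localization_aux:
            v[i] = aux_w
    return v


def localization_distance(
    P: ProteinRecord, Q: ProteinRecord, main_weight: float = 1.0, aux_weight: float = 0.3
) -> float:
    """Cosine distance between weighted compartment-indicator vectors."""
    universe = sorted(
        P.localization_main | P.localization_aux | Q.localization_main | Q.localization_aux
    )
    if not universe:
        return np.nan
    vp = _loc_vector(P, universe, main_weight, aux_weight)
    vq = _loc_vector(Q, universe, main_weight, aux_weight)
    np_, nq = np.linalg.norm(vp), np.linalg.norm(vq)
    if np_ == 0 or nq == 0:
        return np.nan
    return 1.0 - float(vp @ vq / (np_ * nq))


def expression_distance(P: ProteinRecord, Q: ProteinRecord, layer: str = "tissue") -> float:
    """Spearman co-expression distance ``1 - (1 + r_S)/2``."""
    attr = {"tissue": "expression_tissue", "cellline": "expression_cellline"}[layer]
    vp, vq = getattr(P, attr), getattr(Q, attr)
    if vp is None or vq is None:
        return np.nan
    if len(vp) != len(vq) or len(vp) < 3:
        raise LigomapError("expression profiles must share a dimension >= 3")
    if np.ptp(vp) == 0 or np.ptp(vq) == 0:
        return np.nan
    r = spearmanr(vp, vq).statistic
    return 1.0 - (1.0 + r) / 2.0


# ---------------------------------------------------------------------------
# scaling, screening, dataset-level computation
# ---------------------------------------------------------------------------

def scale_unit_interval(
    matrix: DistanceMatrix, impute_policy: str = "median", meta: Optional[dict] = None
) -> DistanceMatrix:
    """Min-max scale a distance matrix to [0, 1].

    Scaling is over defined (non-NaN, finite) off-diagonal entries; +inf
    sentinels map to 1; NaN (undefined) pairs are imputed to the median of
    the defined scaled entries and counted in ``meta``.
    """
    if impute_policy not in ("median",):
        raise LigomapError(f"unknown imputation policy {impute_policy!r}")
    v = matrix.values.copy()
    n = matrix.n
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(v)
    info = {"measure": matrix.measure_id, "n_undefined_pairs": int(np.isnan(v[off]).sum() // 2)}
    if not finite.any():
        raise LigomapError("no defined off-diagonal entries to scale")
    mn, mx = float(v[finite].min()), float(v[finite].max())
    info["min"], info["max"] = mn, mx
    if mx == mn:
        warnings.warn(
            f"{matrix.measure_id}: degenerate scale (all defined entries equal); "
            "returning all-zeros",
            stacklevel=2,
        )
        out = np.zeros_like(v)
    else:
        out = np.where(finite, (v - mn) / (mx - mn), v)
        out[off & np.isinf(v)] = 1.0
        nan_mask = off & np.isnan(v)
        if nan_mask.any():
            med = float(np.median(out[off & ~np.isnan(out)]))
            out[nan_mask] = med
            info["imputed_value"] = med
        np.fill_diagonal(out, 0.0)
        out = np.clip(out, 0.0, 1.0)
    if meta is not None:
        meta.update(info)
    return DistanceMatrix(matrix.labels, out, matrix.measure_id, scaled=True)


def correlation_screen(matrices: Sequence[DistanceMatrix], threshold: float = 0.5):
    """Pearson correlation of vectorized upper triangles, flagging |r| >= threshold."""
    import pandas as pd

    if len(matrices) < 2:
        raise LigomapError("need at least two matrices")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise LigomapError("matrices must share an identical label set")
    iu = np.triu_indices(len(labels), k=1)
    rows = []
    for a, b in itertools.combinations(matrices, 2):
        r = float(pearsonr(a.values[iu], b.values[iu]).statistic)
        rows.append(
            {
                "measure_a": a.measure_id,
                "measure_b": b.measure_id,
                "pearson_r": r,
                "redundant": bool(abs(r) >= threshold),
            }
        )
    return pd.DataFrame(rows)


def _pairwise(ids, fn) -> np.ndarray:
    n = len(ids)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = fn(i, j)
    return v


def compute_all_distances(
    dataset: LigomeDataset,
    measures: Sequence[str] = MEASURE_IDS,
    subst: Optional[SubstitutionMatrix] = None,
    tm_table: Optional[dict] = None,
    scale: bool = True,
    lms_k: int = 5,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    meta: Optional[dict] = None,
) -> dict[str, DistanceMatrix]:
    """Compute (and by default unit-scale) the requested measures for a dataset."""
    subst = subst or SubstitutionMatrix.blosum62()
    recs = dataset.records
    ids = dataset.ids
    aligner = _make_aligner(subst, gap_open, gap_extend)

    sim_cache: dict[tuple[str, str], float] = {}

    def cached_sim(x, y):
        key = (x, y) if x <= y else (y, x)
        if key not in sim_cache:
            sim_cache[key] = term_similarity(x, y, dataset.ontology)
        return sim_cache[key]

    builders = {
        "LMS": lambda i, j: lms_distance(recs[i], recs[j], subst, k=lms_k),
        "gamma": lambda i, j: gamma_distance(recs[i], recs[j], subst, _aligner=aligner),
        "Jac": lambda i, j: jaccard_distance(recs[i], recs[j]),
        "GKgamma": lambda i, j: gk_gamma_distance(recs[i], recs[j]),
        "Dup": lambda i, j: duplication_distance(recs[i], recs[j]),
        "Str": lambda i, j: structural_distance(recs[i], recs[j], tm_table=tm_table),
        "BP": lambda i, j: semantic_distance(recs[i], recs[j], "BP", dataset.ontology, _sim=cached_sim),
        "CC": lambda i, j: semantic_distance(recs[i], recs[j], "CC", dataset.ontology, _sim=cached_sim),
        "MF": lambda i, j: semantic_distance(recs[i], recs[j], "MF", dataset.ontology, _sim=cached_sim),
        "ScL": lambda i, j: localization_distance(recs[i], recs[j]),
        "TE": lambda i, j: expression_distance(recs[i], recs[j], "tissue"),
        "ClE": lambda i, j: expression_distance(recs[i], recs[j], "cellline"),
    }
    out = {}
    for m in measures:
        if m not in builders:
            raise LigomapError(f"unknown measure {m!r}")
        dm = DistanceMatrix(ids, _pairwise(ids, builders[m]), measure_id=m)
        if scale:
            sub_meta: dict = {}
            dm = scale_unit_interval(dm, meta=sub_meta)
            if meta is not None:
                meta[m] = sub_meta
        out[m] = dm
    return out
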