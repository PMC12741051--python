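"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the defining formulas with plain
loops, deliberately sharing no code with the package implementation.
"""

from collections import Counter
from itertools import combinations
from math import exp, log2, sqrt

import numpy as np


def lms_brute(p: str, q: str, score: dict, k: int = 5) -> float:
    """Both-direction best-fragment local matching score by full enumeration."""

    def frag_score(a, b):
        return sum(score[x, y] for x, y in zip(a, b))

    def one_way(a, b):
        total = 0.0
        for i in range(len(a) - k + 1):
            total += max(
                frag_score(a[i : i + k], b[j : j + k]) for j in range(len(b) - k + 1)
            )
        return total

    return one_way(p, q) + one_way(q, p)


def lms_distance_brute(p: str, q: str, score: dict, k: int = 5) -> float:
    return 1.0 - 2.0 * lms_brute(p, q, score, k) / (
        lms_brute(p, p, score, k) + lms_brute(q, q, score, k)
    )


def jaccard_brute(a, b) -> float:
    sa, sb = set(a), set(b)
    return 1.0 - len(sa & sb) / len(sa | sb)


def gk_gamma_brute(arch_p, arch_q):
    """Returns distance or None when undefined (fewer than one ordered pair)."""
    pos_p = {}
    for i, d in enumerate(arch_p):
        if d not in pos_p:
            pos_p[d] = i
    pos_q = {}
    for i, d in enumerate(arch_q):
        if d not in pos_q:
            pos_q[d] = i
    shared = sorted(set(pos_p) & set(pos_q))
    same = rev = 0
    for d1, d2 in combinations(shared, 2):
        if (pos_p[d1] < pos_p[d2]) == (pos_q[d1] < pos_q[d2]):
            same += 1
        else:
            rev += 1
    if same + rev == 0:
        if len(shared) == 1 and set(arch_p) == set(arch_q) == set(shared):
            return 0.0
        return None
    gamma = (same - rev) / (same + rev)
    return 1.0 - (1.0 + gamma) / 2.0


def duplication_brute(arch_p, arch_q):
    cp, cq = Counter(arch_p), Counter(arch_q)
    doms = set(cp) | set(cq)
    if not doms:
        return None
    s = sum(max(cp[d], cq[d]) for d in doms)
    return 1.0 - exp(-sum(abs(cp[d] - cq[d]) for d in doms) / s)


def wang_s_values_brute(term, parents):
    """S_term(t) as the best product of edge weights over all upward paths,
    enumerated exhaustively (parents: term -> [(parent, weight)])."""
    values = {}

    def walk(t, prod):
        if prod > values.get(t, 0.0):
            values[t] = prod
            for p, w in parents.get(t, []):
                walk(p, prod * w)

    walk(term, 1.0)
    return values


def wang_similarity_brute(x, y, parents) -> float:
    sx = wang_s_values_brute(x, parents)
    sy = wang_s_values_brute(y, parents)
    common = set(sx) & set(sy)
    return sum(sx[t] + sy[t] for t in common) / (sum(sx.values()) + sum(sy.values()))


def semantic_distance_brute(terms_p, terms_q, parents) -> float:
    def best(x, others):
        return max(wang_similarity_brute(x, y, parents) for y in others)

    total = sum(best(x, terms_q) for x in terms_p)
    total += sum(best(y, terms_p) for y in terms_q)
    return 1.0 - total / (len(terms_p) + len(terms_q))


def sec_brute(assign_a: dict, assign_b: dict, alpha: float = 0.9) -> float:
    """Element-centric similarity via explicit per-element affinity rows."""
    elements = sorted(assign_a)
    n = len(elements)
    idx = {e: i for i, e in enumerate(elements)}

    def affinity(assign):
        mat = np.zeros((n, n))
        clusters = {}
        for e, c in assign.items():
            clusters.setdefault(c, []).append(e)
        for members in clusters.values():
            for e in members:
                for f in members:
                    mat[idx[e], idx[f]] += alpha / len(members)
        for e in elements:
            mat[idx[e], idx[e]] += 1.0 - alpha
        return mat

    pa, pb = affinity(assign_a), affinity(assign_b)
    s = 1.0 - np.abs(pa - pb).sum(axis=1) / (2.0 * alpha)
    return float(s.mean())


def nmi_fmi_brute(assign_a: dict, assign_b: dict) -> tuple[float, float]:
    """NMI (arithmetic normalization) and FMI from explicit counts."""
    elements = sorted(assign_a)
    n = len(elements)
    ca = {}
    cb = {}
    joint = {}
    for e in elements:
        ca[assign_a[e]] = ca.get(assign_a[e], 0) + 1
        cb[assign_b[e]] = cb.get(assign_b[e], 0) + 1
        key = (assign_a[e], assign_b[e])
        joint[key] = joint.get(key, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * log2(c * n / (ca[a] * cb[b]))
    ha = -sum((c / n) * log2(c / n) for c in ca.values())
    hb = -sum((c / n) * log2(c / n) for c in cb.values())
    nmi = 1.0 if ha + hb == 0 else 2.0 * mi / (ha + hb)
    tp = fp = fn = 0
    for e, f in combinations(elements, 2):
        same_a = assign_a[e] == assign_a[f]
        same_b = assign_b[e] == assign_b[f]
        tp += same_a and same_b
        fp += same_a and not same_b
        fn += same_b and not same_a
    fmi = 0.0 if tp == 0 else tp / sqrt((tp + fp) * (tp + fn))
    return nmi, fmi


def partitions_of(elements):
    """All set partitions of a list (Bell-number many)."""
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for smaller in partitions_of(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def density_peaks_brute(points, d_c, rho_min, delta_min):
    """O(n^2) density-peak clustering written independently with plain loops."""
    pts = np.asarray(points, float)
    n = len(pts)
    dist = [[float(np.hypot(*(pts[i] - pts[j]))) if pts.shape[1] == 2 else float(np.linalg.norm(pts[i] - pts[j])) for j in range(n)] for i in range(n)]
    rho = [sum(1 for j in range(n) if j != i and dist[i][j] < d_c) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-rho[i], i))
    delta = [0.0] * n
    parent = [-1] * n
    maxd = max(max(row) for row in dist)
    for rank, i in enumerate(order):
        if rank == 0:
            delta[i] = maxd
            continue
        best_j, best_d = -1, float("inf")
        for j in order[:rank]:
            if dist[i][j] < best_d:
                best_d, best_j = dist[i][j], j
        delta[i] = best_d
        parent[i] = best_j
    centers = [i for i in range(n) if rho[i] >= rho_min and delta[i] >= delta_min]
    labels = [-1] * n
    for k, c in enumerate(centers):
        labels[c] = k
    for i in order:
        if labels[i] == -1 and parent[i] >= 0:
            labels[i] = labels[parent[i]]
    return centers, labels
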