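"""Clustering-agreement indices.

Element-centric similarity (the metric-learning objective) is authored here
in its hard-partition closed form; NMI and FMI delegate to scikit-learn.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import fowlkes_mallows_score, normalized_mutual_info_score

from .datatypes import LigomapError, Partition


def _check_same_elements(a: Partition, b: Partition):
    if a.elements != b.elements:
        raise LigomapError("partitions must cover the same element set")


def element_centric_similarity(a: Partition, b: Partition, alpha: float = 0.9) -> float:
    """Element-centric clustering similarity of two hard partitions.

    Each element i carries a cluster-affinity row with mass ``alpha/|c(i)|``
    over its cluster mates plus an extra ``1 - alpha`` on itself; per-element
    agreement is one minus the scaled L1 gap between the two rows, and the
    index is the mean over elements. Equals 1 iff the partitions coincide up
    to cluster relabeling.
    """
    _check_same_elements(a, b)
    if not 0.0 < alpha < 1.0:
        raise LigomapError("alpha must lie in (0, 1)")
    elements = a.elements
    ca = {e: c for e, c in a.assignment.items()}
    cb = {e: c for e, c in b.assignment.items()}
    size_a: dict = {}
    size_b: dict = {}
    for e in elements:
        size_a[ca[e]] = size_a.get(ca[e], 0) + 1
        size_b[cb[e]] = size_b.get(cb[e], 0) + 1
    overlap: dict = {}
    for e in elements:
        key = (ca[e], cb[e])
        overlap[key] = overlap.get(key, 0) + 1
    # the (1 - alpha) self terms cancel; only cluster geometry remains
    total = 0.0
    for (cl_a, cl_b), o in overlap.items():
        na, nb = size_a[cl_a], size_b[cl_b]
        l1 = o * abs(1.0 / na - 1.0 / nb) + (na - o) / na + (nb - o) / nb
        total += o * (1.0 - 0.5 * l1)
    return total / len(elements)


def partition_agreement(a: Partition, b: Partition) -> tuple[float, float]:
    """(NMI, FMI) between two hard partitions.

    NMI uses arithmetic-mean normalization; a single-cluster vs
    single-cluster comparison is defined as 1.
    """
    _check_same_elements(a, b)
    la = _as_int_labels(a)
    lb = _as_int_labels(b)
    if a.n_clusters == 1 and b.n_clusters == 1:
        nmi = 1.0
    else:
        nmi = float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))
    fmi = float(fowlkes_mallows_score(la, lb))
    return nmi, fmi


def _as_int_labels(p: Partition) -> np.ndarray:
    mapping: dict = {}
    out = np.empty(len(p.elements), dtype=int)
    for i, e in enumerate(p.elements):
        c = p.assignment[e]
        out[i] = mapping.setdefault(c, len(mapping))
    return out
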