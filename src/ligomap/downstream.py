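"""Downstream scores: substrate-specificity categories, CRISPR essentiality
normalization and calls, compound-cluster propensities, pChEMBL transform,
and density-peak clustering of a 2D chemical embedding."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, ttest_1samp
from sklearn.base import BaseEstimator, ClusterMixin

from .datatypes import LigomapError

ESI_EVIDENCE = ("known", "direct_ppi", "indirect_ppi", "predicted")
#: precedence when a pair is reported by several sources
ESI_PRECEDENCE = {k: i for i, k in enumerate(ESI_EVIDENCE)}


@dataclass
class EsiNetwork:
    """E3-substrate interaction edges plus the E3 -> family map."""

    edges: tuple[tuple[str, str, str, float], ...]  # (e3, substrate, evidence, confidence)
    family: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for e3, sub, ev, _ in self.edges:
            if ev not in ESI_EVIDENCE:
                raise LigomapError(f"unknown ESI evidence {ev!r}")
            if e3 not in self.family:
                raise LigomapError(f"E3 {e3!r} missing from the family map")

    def deduplicated(self) -> dict[tuple[str, str], tuple[str, float]]:
        """One edge per (e3, substrate), keeping the strongest evidence class."""
        best: dict[tuple[str, str], tuple[str, float]] = {}
        for e3, sub, ev, conf in self.edges:
            key = (e3, sub)
            if key not in best or ESI_PRECEDENCE[ev] < ESI_PRECEDENCE[best[key][0]]:
                best[key] = (ev, conf)
        return best


def categorize_substrates(net: EsiNetwork) -> dict[str, str]:
    """Partition substrates into E3-specific / family-specific / promiscuous.

    E3-specific: exactly one distinct E3. Family-specific: two or more E3s,
    all from one family. Promiscuous: E3s spanning two or more families.
    """
    e3s_of: dict[str, set] = {}
    for (e3, sub) in net.deduplicated():
        e3s_of.setdefault(sub, set()).add(e3)
    out = {}
    for sub, e3s in e3s_of.items():
        fams = {net.family[e] for e in e3s}
        if len(e3s) == 1:
            out[sub] = "E3-specific"
        elif len(fams) == 1:
            out[sub] = "family-specific"
        else:
            out[sub] = "promiscuous"
    return out


# ---------------------------------------------------------------------------
# CRISPR essentiality
# ---------------------------------------------------------------------------

def guide_nrc(counts: np.ndarray) -> np.ndarray:
    """Normalized read counts: ``log2(count * n * 100 / total + 1)`` per guide."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise LigomapError("read counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise LigomapError("all-zero sample")
    return np.log2(c * len(c) * 100.0 / total + 1.0)


def gene_lfc_and_calls(
    table: pd.DataFrame,
    library_col: str = "library",
    endpoint_cols: Optional[Sequence[str]] = None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log-fold change, p, FDR, and essentiality call.

    ``table`` has one row per guide with columns ``gene``, a library count
    column, and one endpoint count column per replicate. Per-guide LFC is
    endpoint NRC minus library NRC; gene LFC averages over guides and
    replicates; p comes from a two-sided one-sample t-test on the
    replicate-level gene LFCs (an unmoderated stand-in for an empirical-Bayes
    linear model), corrected by Benjamini-Hochberg. Essential iff
    ``|LFC| >= lfc_threshold`` and ``FDR <= fdr_threshold``.
    """
    if endpoint_cols is None:
        endpoint_cols = [c for c in table.columns if c.startswith("endpoint")]
    if len(endpoint_cols) < 2:
        raise LigomapError("need at least two endpoint replicates for testing")
    if table.groupby("gene").size().min() < 1:
        raise LigomapError("every gene needs at least one guide")
    nrc_lib = guide_nrc(table[library_col].to_numpy())
    rep_lfcs = pd.DataFrame(
        {rep: guide_nrc(table[rep].to_numpy()) - nrc_lib for rep in endpoint_cols},
        index=table.index,
    )
    rep_lfcs["gene"] = table["gene"].to_numpy()
    per_gene = rep_lfcs.groupby("gene").mean()  # gene x replicate
    lfc = per_gene.mean(axis=1)
    t = ttest_1samp(per_gene.to_numpy(), 0.0, axis=1)
    p = pd.Series(t.pvalue, index=per_gene.index)
    fdr = pd.Series(false_discovery_control(p.to_numpy(), method="bh"), index=p.index)
    essential = (lfc.abs() >= lfc_threshold) & (fdr <= fdr_threshold)
    return pd.DataFrame(
        {"lfc": lfc, "p": p, "fdr": fdr, "essential": essential}
    ).sort_index()


# ---------------------------------------------------------------------------
# compound clusters
# ---------------------------------------------------------------------------

def propensity(counts: pd.DataFrame) -> pd.DataFrame:
    """Log2 propensity of compound cluster i for target j.

    ``LP_ij = log2[(n_ij / sum_j n_ij) * (sum_ij n_ij / sum_i n_ij)]``;
    zero cells are masked as NaN.
    """
    n = counts.to_numpy(dtype=float)
    if (n < 0).any():
        raise LigomapError("counts must be non-negative")
    row = n.sum(axis=1, keepdims=True)
    if (row == 0).any():
        raise LigomapError("all-zero cluster row")
    col = n.sum(axis=0, keepdims=True)
    total = n.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log2((n / row) * (total / col))
    lp[n == 0] = np.nan
    return pd.DataFrame(lp, index=counts.index, columns=counts.columns)


def p_activity(activity_molar: float) -> float:
    """pChEMBL: ``-log10`` of a molar potency; 1 uM maps to 6.0."""
    if activity_molar <= 0:
        raise LigomapError("activity must be positive")
    return -float(np.log10(activity_molar))


def is_active(activity_molar: float, threshold: float = 6.0) -> bool:
    """Early-screening activity filter: pChEMBL >= threshold (default 6.0)."""
    return p_activity(activity_molar) >= threshold


def density_peak_clusters(
    points: np.ndarray,
    d_c: float = 0.05,
    rho_min: int = 20,
    delta_min: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Density-peak clustering of a normalized 2D embedding.

    ``rho_i`` counts points within ``d_c`` (cutoff kernel, excluding self);
    ``delta_i`` is the distance to the nearest higher-density point (the
    global density maximum takes the maximum pairwise distance). Centers are
    points with ``rho >= rho_min`` and ``delta >= delta_min``; every other
    point inherits the cluster of its nearest higher-density neighbor via a
    descending-density sweep. Unassignable points get label -1.

    Returns (center indices, labels, per-point table with rho/delta).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise LigomapError("need an (n >= 2, d) coordinate array")
    if d_c <= 0:
        raise LigomapError("d_c must be positive")
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    n = len(x)
    rho = (dist < d_c).sum(axis=1) - 1
    order = np.lexsort((np.arange(n), -rho))  # descending rho, ties by index
    delta = np.empty(n)
    nn_higher = np.full(n, -1)
    max_dist = dist.max()
    for rank, i in enumerate(order):
        if rank == 0:
            delta[i] = max_dist
            continue
        higher = order[:rank]
        j = higher[np.argmin(dist[i, higher])]
        delta[i] = dist[i, j]
        nn_higher[i] = j
    centers = np.where((rho >= rho_min) & (delta >= delta_min))[0]
    labels = np.full(n, -1)
    for k, c in enumerate(centers):
        labels[c] = k
    for i in order:
        if labels[i] == -1 and nn_higher[i] >= 0:
            labels[i] = labels[nn_higher[i]]
    table = pd.DataFrame({"rho": rho, "delta": delta, "label": labels})
    return centers, labels, table


class DensityPeakClustering(ClusterMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`density_peak_clusters`.

    Parameters mirror the function; coordinates are min-max normalized per
    axis before clustering when ``normalize=True``.
    """

    def __init__(
        self,
        d_c: float = 0.05,
        rho_min: int = 20,
        delta_min: float = 0.1,
        normalize: bool = True,
    ):
        self.d_c = d_c
        self.rho_min = rho_min
        self.delta_min = delta_min
        self.normalize = normalize

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        if self.normalize:
            mn, mx = x.min(axis=0), x.max(axis=0)
            span = np.where(mx > mn, mx - mn, 1.0)
            x = (x - mn) / span
        self.centers_, self.labels_, self.table_ = density_peak_clusters(
            x, d_c=self.d_c, rho_min=self.rho_min, delta_min=self.delta_min
        )
        return self
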