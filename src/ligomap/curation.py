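"""Ligome-assembly logic: cross-source consensus scores, catalytic-domain
filtering, and complex/standalone mode annotation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .datatypes import LigomapError, LigomeDataset

ROLES = ("adaptor", "receptor", "scaffold", "E3", "other")
EVIDENCE_KINDS = ("structure_complex", "binary_ppi")
#: roles whose interaction with an E3 implies complex-mode operation
_COMPLEX_PARTNERS = frozenset({"adaptor", "receptor", "scaffold"})


@dataclass
class InteractionEvidence:
    """Edges between E3s and non-catalytic subunits plus a role map."""

    edges: tuple[tuple[str, str, str, float], ...]  # (a, b, kind, confidence)
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for a, b, kind, conf in self.edges:
            if kind not in EVIDENCE_KINDS:
                raise LigomapError(f"unknown evidence kind {kind!r}")
            if not 0.0 <= conf <= 1.0:
                raise LigomapError(f"confidence out of [0, 1] on edge ({a}, {b})")
        for p, r in self.roles.items():
            if r not in ROLES:
                raise LigomapError(f"unknown role {r!r} for {p}")


def consensus_score(membership: Sequence[bool]) -> float:
    """Fraction of source datasets containing the protein."""
    if len(membership) == 0:
        raise LigomapError("need at least one source")
    return sum(bool(m) for m in membership) / len(membership)


def consensus_table(dataset: LigomeDataset) -> pd.Series:
    """Per-protein consensus scores from the dataset's source-membership table."""
    sm = dataset.source_membership
    if sm is None:
        raise LigomapError("dataset has no source-membership table")
    return sm.astype(bool).mean(axis=1)


def catalytic_filter(
    dataset: LigomeDataset, catalytic: Optional[frozenset] = None
) -> tuple[list[str], pd.Series]:
    """Retain proteins carrying at least one catalytic domain.

    Returns the retained (E3) ids plus a per-protein verdict series with
    values 'E3', 'non-catalytic', or 'no-annotation'.
    """
    c = frozenset(catalytic if catalytic is not None else dataset.catalytic_domains)
    if not c:
        raise LigomapError("catalytic domain set is empty")
    verdicts = {}
    for r in dataset.records:
        if not r.architecture:
            verdicts[r.id] = "no-annotation"
        elif r.unique_domains & c:
            verdicts[r.id] = "E3"
        else:
            verdicts[r.id] = "non-catalytic"
    retained = [i for i, v in verdicts.items() if v == "E3"]
    return retained, pd.Series(verdicts, name="verdict")


def annotate_mode(
    e3_ids: Sequence[str],
    evidence: InteractionEvidence,
    prior_standalone: frozenset = frozenset(),
    min_conf: float = 0.5,
) -> dict[str, str]:
    """Classify each E3 as complex / standalone / unclassified.

    Complex: any structure-resolved complex edge, or any binary PPI with
    confidence >= ``min_conf``, to an adaptor/receptor/scaffold. Otherwise
    standalone if in the prior-standalone set, else unclassified.
    """
    partners: dict[str, list[tuple[str, str, float]]] = {e: [] for e in e3_ids}
    for a, b, kind, conf in evidence.edges:
        for e3, other in ((a, b), (b, a)):
            if e3 in partners:
                partners[e3].append((other, kind, conf))
    out = {}
    for e3 in e3_ids:
        is_complex = any(
            evidence.roles.get(other) in _COMPLEX_PARTNERS
            and (kind == "structure_complex" or conf >= min_conf)
            for other, kind, conf in partners[e3]
        )
        if is_complex:
            out[e3] = "complex"
        elif e3 in prior_standalone:
            out[e3] = "standalone"
        else:
            out[e3] = "unclassified"
    return out
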