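"""Second-level agglomeration of sequence clusters into network units.

First-level clusters (e.g. swarms of near-identical amplicons) are merged
whenever their representative sequences are at least ``threshold`` percent
identical, taking connected components of the thresholded similarity graph.
The resulting network sequence clusters (NSCs) are the node units for all
downstream network inference; merging them first prevents several clusters of
the same organism from inflating the network with trivially correlated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NSCAssignment",
    "build_nscs",
    "aggregate_counts",
    "filter_min_abundance",
    "filter_allowlist",
]


@dataclass
class NSCAssignment:
    """Mapping of input cluster ids to network sequence cluster (NSC) ids.

    Each NSC is named after its lexicographically smallest member, so the
    labeling is canonical: independent of input row order.
    """

    member_map: dict[str, str]
    nsc_ids: list[str]


def _check_similarity(sim: pd.DataFrame) -> None:
    if not sim.index.equals(sim.columns):
        raise ValueError("similarity matrix row and column ids differ")
    vals = sim.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("similarity matrix is not symmetric")


def build_nscs(sim: pd.DataFrame, threshold: float = 97.0) -> NSCAssignment:
    """Group sequences into NSCs by single-linkage at ``threshold`` identity.

    An edge joins two sequences whenever their pairwise identity is at least
    ``threshold`` (inclusive); NSCs are the connected components, so linkage
    is transitive: A–B and B–C at 97%+ merge A, B, C even if A–C is below.
    """
    if sim.shape[0] == 0:
        return NSCAssignment(member_map={}, nsc_ids=[])
    _check_similarity(sim)
    ids = list(sim.index)
    adj = csr_matrix(sim.to_numpy(dtype=float) >= threshold)
    _, labels = connected_components(adj, directed=False)

    members_by_label: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        members_by_label.setdefault(int(lab), []).append(sid)

    member_map: dict[str, str] = {}
    for members in members_by_label.values():
        nsc = min(members)
        for sid in members:
            member_map[sid] = nsc
    return NSCAssignment(member_map=member_map, nsc_ids=sorted(set(member_map.values())))


def aggregate_counts(counts: pd.DataFrame, assignment: NSCAssignment) -> pd.DataFrame:
    """Sum member rows of each NSC; total reads are conserved."""
    missing = [rid for rid in counts.index if rid not in assignment.member_map]
    if missing:
        raise ValueError(f"count rows not in assignment: {missing[:5]}")
    grouped = counts.groupby(counts.index.map(assignment.member_map), sort=False).sum()
    out = grouped.reindex([i for i in assignment.nsc_ids if i in grouped.index])
    out.index.name = counts.index.name or "id"
    return out


def filter_min_abundance(counts: pd.DataFrame, min_total: int = 3) -> pd.DataFrame:
    """Drop rows whose total read count is below ``min_total``.

    The boundary is inclusive: a row totalling exactly ``min_total`` survives
    (only strictly rarer clusters are discarded). Row order is preserved.
    """
    return counts.loc[counts.sum(axis=1) >= min_total]


def filter_allowlist(counts: pd.DataFrame, keep_ids) -> pd.DataFrame:
    """Retain only rows named in a precomputed keep-list.

    Stands in for reference-database retention screens (e.g. keeping clusters
    with an adequate match in a taxonomy database), which require external
    resources: the screen itself happens elsewhere, its outcome is applied
    here.
    """
    keep = set(keep_ids)
    return counts.loc[[rid for rid in counts.index if rid in keep]]
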