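"""Species-extinction scenarios: cascading targeted attacks on a network.

The robustness of a community network is probed by removing nodes one at a
time in decreasing order of betweenness centrality, *recomputing* betweenness
after every removal (a cascading attack), and recording the cumulative loss
of connectivity. The primary loss metric is the fraction of the network's
initial edges eliminated; the fraction of initially connected node pairs
disconnected is carried as a secondary column, since both readings of
"connectivity loss" appear in the robustness literature.

This is a hypothetical whole-network stress test: it says nothing about the
likelihood that any particular species actually goes extinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .topology import betweenness

__all__ = ["AttackCurve", "cascading_attack", "attack_summary"]


@dataclass
class AttackCurve:
    """Per-removal-step record of a cascading attack.

    ``steps`` columns: rank (1-based), removed_node, betweenness_at_removal,
    edges_remaining, loss_fraction (edge loss, primary), pair_loss_fraction
    (connected-pair loss, secondary).
    """

    steps: pd.DataFrame
    initial_edges: int
    initial_connected_pairs: int

    def to_csv(self) -> str:
        return self.steps.to_csv(index=False)


def _connected_pairs(net: nx.Graph) -> int:
    return sum(
        len(c) * (len(c) - 1) // 2 for c in nx.connected_components(net)
    )


def cascading_attack(net: nx.Graph, n_removals: int | None = None) -> AttackCurve:
    """Remove the current highest-betweenness node, step by step.

    Ties in betweenness are broken toward the lexicographically smallest node
    id, making the whole trajectory deterministic. Nodes isolated by earlier
    removals stay in the graph; only explicit removals count toward the rank.
    Edge loss is measured against the initial edge count, so the curve is
    non-decreasing and reaches 1 when every edge-bearing node is gone.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if n_removals is None:
        n_removals = net.number_of_nodes()
    if n_removals > net.number_of_nodes():
        raise ValueError("n_removals exceeds the number of nodes")

    work = net.copy()
    e0 = net.number_of_edges()
    p0 = _connected_pairs(net)
    records = []
    for rank in range(1, n_removals + 1):
        btw = betweenness(work)
        target = min(btw, key=lambda node: (-btw[node], str(node)))
        score = btw[target]
        work.remove_node(target)
        e_rem = work.number_of_edges()
        p_rem = _connected_pairs(work)
        records.append(
            {
                "rank": rank,
                "removed_node": target,
                "betweenness_at_removal": score,
                "edges_remaining": e_rem,
                "loss_fraction": 1.0 - e_rem / e0 if e0 else 1.0,
                "pair_loss_fraction": 1.0 - p_rem / p0 if p0 else 1.0,
            }
        )
    return AttackCurve(
        steps=pd.DataFrame.from_records(records),
        initial_edges=e0,
        initial_connected_pairs=p0,
    )


def attack_summary(
    curve: AttackCurve, loss_levels: tuple[float, ...] = (0.5, 0.95)
) -> dict[float, int]:
    """Removals needed to reach each connectivity-loss level.

    For each level, the smallest removal rank whose edge-loss fraction
    reaches the level; levels never reached within the curve are absent from
    the result.
    """
    if curve.steps.shape[0] == 0:
        raise ValueError("empty attack curve")
    out: dict[float, int] = {}
    for level in loss_levels:
        if not 0.0 < level <= 1.0:
            raise ValueError(f"loss level outside (0, 1]: {level}")
        hit = curve.steps.loc[curve.steps["loss_fraction"] >= level, "rank"]
        if len(hit):
            out[level] = int(hit.iloc[0])
    return out


def summary_json(curve: AttackCurve, loss_levels: tuple[float, ...] = (0.5, 0.95)) -> str:
    summary = attack_summary(curve, loss_levels)
    payload = {
        "initial_edges": curve.initial_edges,
        "initial_connected_pairs": curve.initial_connected_pairs,
        "n_removals": int(curve.steps.shape[0]),
        "final_loss_fraction": float(curve.steps["loss_fraction"].iloc[-1]),
        "removals_to_loss_level": {str(k): v for k, v in summary.items()},
    }
    return json.dumps(payload, indent=2, sort_keys=True)
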