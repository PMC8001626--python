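"""Keystone-node detection: bootstrapped betweenness plus articulation points.

A key (keystone) node is one whose betweenness centrality is significantly
higher than expected for the network as a whole *and* whose removal would
fragment the network (an articulation point). Significance is assessed by
bootstrapping the vector of betweenness scores: resampling with replacement
approximately normalizes the distribution of the mean, and a node is
significant when its score exceeds the upper bound of the central 95%
percentile interval of the bootstrapped mean. When all scores are equal the
interval collapses onto the common value and no node is significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .topology import articulation_points, betweenness

__all__ = ["KeyNodeReport", "find_key_nodes"]


@dataclass
class KeyNodeReport:
    """Per-node keystone calls plus the bootstrap evidence behind them."""

    table: pd.DataFrame  # betweenness, is_articulation, significant, is_key
    ci_lower: float
    ci_upper: float
    n_boot: int
    ci: float
    seed: int
    method: str = "percentile bootstrap of the mean betweenness"
    extra: dict = field(default_factory=dict)

    @property
    def key_nodes(self) -> list:
        return list(self.table.index[self.table["is_key"]])

    def summary_json(self) -> str:
        payload = {
            "n_nodes": int(self.table.shape[0]),
            "n_key_nodes": int(self.table["is_key"].sum()),
            "key_nodes": [str(k) for k in self.key_nodes],
            "ci": self.ci,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "method": self.method,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def find_key_nodes(
    net: nx.Graph,
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
) -> KeyNodeReport:
    """Call keystone nodes on a network.

    Bootstraps the betweenness vector ``n_boot`` times, takes the central
    ``ci`` percentile interval of the resampled mean, and flags nodes whose
    betweenness exceeds its upper bound; a keystone is a flagged node that is
    also an articulation point.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes for keystone detection")
    if not 0.0 < ci < 1.0:
        raise ValueError("ci must lie in (0, 1)")

    nodes = sorted(net.nodes, key=str)
    btw = betweenness(net)
    scores = np.array([btw[n] for n in nodes], dtype=float)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(nodes), size=(n_boot, len(nodes)))
    boot_means = scores[idx].mean(axis=1)
    tail = (1.0 - ci) / 2.0
    ci_lower, ci_upper = np.quantile(boot_means, [tail, 1.0 - tail])

    arts = articulation_points(net)
    significant = scores > ci_upper
    is_art = np.array([n in arts for n in nodes])
    table = pd.DataFrame(
        {
            "betweenness": scores,
            "is_articulation": is_art,
            "significant": significant,
            "is_key": significant & is_art,
        },
        index=pd.Index(nodes, name="id"),
    )
    return KeyNodeReport(
        table=table,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        n_boot=n_boot,
        ci=ci,
        seed=seed,
    )
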