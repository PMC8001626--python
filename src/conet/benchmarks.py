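"""Reference experiments on synthetic data with known ground truth.

Small, self-contained studies used to validate the inference pipeline:
null-model calibration on independent data, planted-guild edge recovery and
partition accuracy, and the targeted-attack benchmark. Shared between the
test suite and the reproduction script.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from ._util import derive_seed
from .network import build_consensus, determine_thresholds
from .preprocessing import append_env, normalize, prevalence_filter
from .robustness import cascading_attack
from .synthetic import SyntheticSpec, generate_counts

__all__ = [
    "null_calibration",
    "planted_recovery",
    "two_guild_benchmark_graph",
    "targeted_vs_random_loss",
]


def null_calibration(
    seed: int,
    n_taxa: int = 500,
    n_samples: int = 36,
    n_permutations: int = 200,
    alpha: float = 0.01,
    n_jitter: int = 100,
) -> dict:
    """Consensus edge fraction on fully independent synthetic data.

    With no planted guilds every detected edge is a false positive; a
    calibrated null model keeps the consensus edge fraction near ``alpha``
    of the tested pairs.
    """
    spec = SyntheticSpec(
        n_samples=n_samples,
        n_taxa=n_taxa,
        n_guilds=0,
        guild_size=0,
        n_env_params=0,
        env_linked_guilds=(),
        noise_taxa_fraction=0.0,
        seed=derive_seed(seed, "calibration-data"),
    )
    counts, _, _ = generate_counts(spec)
    filtered = prevalence_filter(counts)
    norm = normalize(filtered)
    thresholds = determine_thresholds(
        norm,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=derive_seed(seed, "calibration-thresholds"),
    )
    net = build_consensus(
        norm, thresholds, n_jitter=n_jitter, seed=derive_seed(seed, "calibration-consensus")
    )
    n_rows = norm.values.shape[0]
    n_pairs = n_rows * (n_rows - 1) // 2
    return {
        "n_rows": n_rows,
        "n_pairs": n_pairs,
        "n_edges": net.number_of_edges(),
        "edge_fraction": net.number_of_edges() / n_pairs,
        "rho_pos": thresholds.rho_pos,
        "rho_neg": thresholds.rho_neg,
    }


def planted_recovery(
    seed: int,
    n_permutations: int = 200,
    n_jitter: int = 100,
    alpha: float = 0.01,
) -> dict:
    """Edge recovery and guild-partition accuracy on planted-guild data.

    Uses the generator defaults (4 guilds x 10 taxa at within-guild Spearman
    0.9, 36 samples, 500 taxa); reports the fraction of planted within-guild
    edges present in the consensus network and the adjusted Rand index
    between seeded Louvain communities and the true guild labels over the
    guild members in the network.
    """
    spec = SyntheticSpec(seed=derive_seed(seed, "recovery-data"))
    counts, env, truth = generate_counts(spec)
    filtered = prevalence_filter(counts)
    norm = append_env(normalize(filtered), env)
    thresholds = determine_thresholds(
        norm,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=derive_seed(seed, "recovery-thresholds"),
    )
    net = build_consensus(
        norm, thresholds, n_jitter=n_jitter, seed=derive_seed(seed, "recovery-consensus")
    )
    recovered = {tuple(sorted(e)) for e in net.edges}
    recovery = len(truth.planted_edges & recovered) / len(truth.planted_edges)

    communities = nx.community.louvain_communities(
        net, seed=derive_seed(seed, "recovery-louvain")
    )
    label = {n: i for i, c in enumerate(communities) for n in c}
    guild_nodes = [
        n for n in net.nodes if truth.guild_membership.get(n) is not None
    ]
    ari = _adjusted_rand_index(
        [truth.guild_membership[n] for n in guild_nodes],
        [label[n] for n in guild_nodes],
    )
    return {
        "n_planted_edges": len(truth.planted_edges),
        "edge_recovery": recovery,
        "ari": ari,
        "n_guild_nodes_in_network": len(guild_nodes),
        "n_edges": net.number_of_edges(),
    }


def _adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    from collections import Counter

    n = len(labels_a)
    pairs = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = sum(comb2(c) for c in pairs.values())
    sum_a = sum(comb2(c) for c in a_counts.values())
    sum_b = sum(comb2(c) for c in b_counts.values())
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def two_guild_benchmark_graph(
    seed: int = 17, size: int = 12, p: float = 0.6, bridge_links: int = 6
) -> nx.Graph:
    """Two dense communities joined by a single bridging hub.

    The hub connects ``bridge_links`` members of each community, making it
    the unique high-betweenness articulation node — the structure a keystone
    detector and a targeted attack are meant to exploit.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    for offset in (0, size):
        members = list(range(offset, offset + size))
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if rng.random() < p:
                    g.add_edge(a, b)
    for side in (0, size):
        for k in range(bridge_links):
            g.add_edge(side + k, "bridge")
    return g


def targeted_vs_random_loss(
    graph: nx.Graph,
    n_steps: int = 10,
    n_random_orders: int = 50,
    seed: int = 0,
) -> dict:
    """Cumulative edge loss of a targeted attack vs random removal orders."""
    targeted = cascading_attack(graph, n_removals=n_steps)
    targeted_loss = float(targeted.steps["loss_fraction"].sum())

    rng = np.random.default_rng(seed)
    e0 = graph.number_of_edges()
    random_losses = []
    for _ in range(n_random_orders):
        order = list(graph.nodes)
        rng.shuffle(order)
        h = graph.copy()
        cum = 0.0
        for node in order[:n_steps]:
            h.remove_node(node)
            cum += 1.0 - h.number_of_edges() / e0
        random_losses.append(cum)
    return {
        "targeted_cumulative_loss": targeted_loss,
        "random_mean_cumulative_loss": float(np.mean(random_losses)),
        "n_steps": n_steps,
        "n_random_orders": n_random_orders,
    }
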