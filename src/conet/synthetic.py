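"""Synthetic metabarcoding data with planted co-occurrence structure.

Generates taxa-by-sample read-count tables in which chosen groups of taxa
("guilds") have rank-correlated abundance profiles, plus environmental
parameters tracking selected guilds and a ground-truth record of everything
planted. The generator emulates the shape of a seasonal lake time series:
a few dozen biweekly samples, heavy-tailed taxon abundances, variable
sequencing depth, and a fraction of sparse noise taxa.

Rank correlation is planted through a Gaussian copula: guild members share a
latent factor whose loading is chosen so the *pairwise* Spearman correlation
between members equals ``within_guild_rho`` exactly in the latent field.
Because downstream inference is rank-based, the planted effect survives any
monotone normalization applied later.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_counts",
    "generate_similarity_matrix",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror one seasonal dataset of a biweekly three-year lake survey
    at reduced taxon count: 36 samples, 500 taxa of which 4 guilds x 10 taxa
    carry planted structure, strongly correlated within guilds (Spearman 0.9),
    5 environmental parameters of which 2 track a guild, mean sequencing depth
    50,000 reads with 30% coefficient of variation, and 20% sparse noise taxa.
    """

    n_samples: int = 36
    n_taxa: int = 500
    n_guilds: int = 4
    guild_size: int = 10
    within_guild_rho: float = 0.9
    n_env_params: int = 5
    env_linked_guilds: tuple[int, ...] = (0, 1)
    depth_mean: float = 50_000.0
    depth_cv: float = 0.3
    noise_taxa_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_taxa <= 0:
            raise ValueError("n_samples and n_taxa must be positive")
        if self.n_guilds < 0 or self.guild_size < 0 or self.n_env_params < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.within_guild_rho <= 1.0:
            raise ValueError("within_guild_rho must lie in [0, 1]")
        if not 0.0 <= self.noise_taxa_fraction <= 1.0:
            raise ValueError("noise_taxa_fraction must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be non-negative")
        n_guild_taxa = self.n_guilds * self.guild_size
        if n_guild_taxa > self.n_taxa:
            raise ValueError("n_guilds * guild_size exceeds n_taxa")
        if n_guild_taxa + round(self.noise_taxa_fraction * self.n_taxa) > self.n_taxa:
            raise ValueError("guild taxa plus noise taxa exceed n_taxa")
        for g in self.env_linked_guilds:
            if not 0 <= g < max(self.n_guilds, 1):
                raise ValueError(f"env_linked_guilds references unknown guild {g}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``latent`` holds the pre-resampling latent abundance field (log scale);
    it is carried for test oracles and is not part of the JSON serialization.
    """

    guild_membership: dict[str, int | None]
    planted_edges: frozenset[tuple[str, str]]
    env_links: frozenset[tuple[str, int]]
    latent: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def to_json(self) -> str:
        payload = {
            "guild_membership": self.guild_membership,
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "env_links": sorted([p, g] for p, g in self.env_links),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(
            guild_membership={
                k: (None if v is None else int(v))
                for k, v in payload["guild_membership"].items()
            },
            planted_edges=frozenset(tuple(e) for e in payload["planted_edges"]),
            env_links=frozenset((p, int(g)) for p, g in payload["env_links"]),
        )


def _pairwise_edges(members: list[str]) -> set[tuple[str, str]]:
    return {tuple(sorted(p)) for p in itertools.combinations(members, 2)}


def generate_counts(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a count table, an environmental table, and their ground truth.

    The procedure:

    1. one latent Gaussian factor per guild per sample;
    2. guild members get latent profiles correlated with the factor at a
       loading chosen (via the Gaussian-copula relation
       ``r = 2 sin(pi * rho_s / 6)``) so every within-guild pair has Spearman
       correlation ``within_guild_rho``;
    3. independent background taxa, plus sparse noise taxa present in only a
       random minority of samples;
    4. heavy-tailed (log-normal) base abundances, then multinomial resampling
       of each sample to a depth drawn log-normally at the requested mean and
       coefficient of variation.

    Environmental parameters linked to a guild are monotone (linear) in the
    guild's latent factor plus measurement noise; the rest are independent.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_samples
    n_guild_taxa = spec.n_guilds * spec.guild_size
    n_noise = round(spec.noise_taxa_fraction * spec.n_taxa)
    n_background = spec.n_taxa - n_guild_taxa - n_noise

    taxon_ids = [f"t{i:05d}" for i in range(spec.n_taxa)]
    sample_ids = [f"s{j:03d}" for j in range(n)]

    # Pairwise Spearman rho_s between two standard normals with Pearson
    # correlation r is (6/pi) asin(r/2); invert to hit the requested rho_s.
    r_latent = 2.0 * np.sin(np.pi * spec.within_guild_rho / 6.0)
    loading = np.sqrt(r_latent)

    factors = rng.standard_normal((max(spec.n_guilds, 1), n))
    if 1 < spec.n_guilds < n:
        # Orthogonalize the realized factor vectors (after centering) so the
        # between-guild correlation is exactly zero in-sample: otherwise
        # chance correlation between two factors at small n shifts every
        # cross-guild pair at once and the planted truth ("within-guild
        # pairs correlated, all others independent") would not hold.
        centered = factors[: spec.n_guilds] - factors[: spec.n_guilds].mean(
            axis=1, keepdims=True
        )
        q, _ = np.linalg.qr(centered.T)
        factors[: spec.n_guilds] = (q * np.sqrt(n)).T
    latent = np.empty((spec.n_taxa, n))
    membership: dict[str, int | None] = {}
    planted: set[tuple[str, str]] = set()

    row = 0
    for g in range(spec.n_guilds):
        members = taxon_ids[row : row + spec.guild_size]
        eps = rng.standard_normal((spec.guild_size, n))
        latent[row : row + spec.guild_size] = (
            loading * factors[g] + np.sqrt(1.0 - r_latent) * eps
        )
        for t in members:
            membership[t] = g
        planted |= _pairwise_edges(members)
        row += spec.guild_size
    # independent taxa: background then noise
    n_indep = n_background + n_noise
    if n_indep:
        latent[row : row + n_indep] = rng.standard_normal((n_indep, n))
    for t in taxon_ids[n_guild_taxa:]:
        membership[t] = None

    # Heavy-tailed base abundance across taxa: log-normal, sigma = 1.5.
    # Kept below the regime where a single taxon dominates sample totals,
    # which would couple all relative abundances through the shared
    # denominator and break the independence of unplanted taxa.
    base_log = rng.normal(0.0, 1.5, size=spec.n_taxa)
    # Guild members emulate the network-forming fraction of the community
    # (abundant, prevalent taxa); they draw from the upper part of the
    # abundance distribution so the planted rank correlation is not drowned
    # by read-sampling noise on near-zero counts.
    if n_guild_taxa:
        base_log[:n_guild_taxa] = rng.normal(1.5, 1.0, size=n_guild_taxa)
    abundance = np.exp(base_log[:, None] + latent)

    # noise taxa occur in few samples only (exercises prevalence filtering)
    if n_noise:
        presence_p = rng.uniform(1.0 / n, 0.25, size=n_noise)
        mask = rng.random((n_noise, n)) < presence_p[:, None]
        # guarantee at least one occurrence so the taxon exists at all
        empty = ~mask.any(axis=1)
        mask[empty, rng.integers(0, n, size=int(empty.sum()))] = True
        abundance[spec.n_taxa - n_noise :] *= mask

    # per-sample depths: log-normal at requested mean / CV (degenerate CV=0)
    if spec.depth_cv > 0:
        sigma2 = np.log1p(spec.depth_cv**2)
        mu = np.log(spec.depth_mean) - sigma2 / 2.0
        depths = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    else:
        depths = np.full(n, spec.depth_mean)
    depths = np.maximum(np.rint(depths).astype(np.int64), 1)

    counts = np.empty((spec.n_taxa, n), dtype=np.int64)
    for j in range(n):
        p = abundance[:, j] / abundance[:, j].sum()
        counts[:, j] = rng.multinomial(depths[j], p)

    count_table = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    count_table.index.name = "id"

    env_ids = [f"env{k}" for k in range(spec.n_env_params)]
    env_vals = np.empty((spec.n_env_params, n))
    env_links: set[tuple[str, int]] = set()
    linked = list(spec.env_linked_guilds)
    for k in range(spec.n_env_params):
        if k < len(linked) and spec.n_guilds > 0:
            g = linked[k]
            env_vals[k] = 10.0 + 5.0 * factors[g] + 0.5 * rng.standard_normal(n)
            env_links.add((env_ids[k], g))
        else:
            env_vals[k] = rng.normal(10.0, 5.0, size=n)
    env_table = pd.DataFrame(env_vals, index=env_ids, columns=sample_ids)
    env_table.index.name = "id"

    latent_table = pd.DataFrame(
        base_log[:, None] + latent, index=taxon_ids, columns=sample_ids
    )
    truth = SyntheticTruth(
        guild_membership=membership,
        planted_edges=frozenset(planted),
        env_links=frozenset(env_links),
        latent=latent_table,
    )
    return count_table, env_table, truth


def generate_similarity_matrix(
    n_sequences: int,
    n_true_clusters: int,
    within_identity: float,
    between_identity: float,
    seed: int,
) -> pd.DataFrame:
    """Pairwise percent-identity matrix with planted clusters.

    Sequences are assigned round-robin to ``n_true_clusters`` clusters; pairs
    within a cluster get identity in [within_identity, 100], pairs across
    clusters get identity at most ``between_identity``. Symmetric, diagonal
    100. Thresholding between the two bands recovers the planted clusters as
    connected components.
    """
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    if n_true_clusters <= 0 or n_true_clusters > n_sequences:
        raise ValueError("n_true_clusters must lie in [1, n_sequences]")
    if within_identity <= between_identity:
        raise ValueError("within_identity must exceed between_identity")

    rng = np.random.default_rng(seed)
    ids = [f"seq{i:04d}" for i in range(n_sequences)]
    cluster = np.arange(n_sequences) % n_true_clusters

    low = max(0.0, between_identity - 15.0)
    identity = rng.uniform(low, between_identity, size=(n_sequences, n_sequences))
    same = cluster[:, None] == cluster[None, :]
    within = rng.uniform(within_identity, 100.0, size=(n_sequences, n_sequences))
    identity[same] = within[same]
    identity = np.triu(identity, 1)
    identity = identity + identity.T
    np.fill_diagonal(identity, 100.0)

    sim = pd.DataFrame(identity, index=ids, columns=ids)
    sim.index.name = "id"
    return sim
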