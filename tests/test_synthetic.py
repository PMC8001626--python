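"""Generator tests: determinism, planted structure, depth conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from conet import SyntheticSpec, generate_counts, generate_similarity_matrix
from conet.network import spearman_matrix


def test_seed_determines_output_bit_identically():
    spec = SyntheticSpec(n_taxa=50, n_samples=20, n_guilds=2, guild_size=5, seed=9)
    c1, e1, t1 = generate_counts(spec)
    c2, e2, t2 = generate_counts(spec)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(e1, e2)
    assert t1.planted_edges == t2.planted_edges
    assert t1.guild_membership == t2.guild_membership


def test_column_sums_equal_drawn_depths_and_counts_nonnegative(small_dataset):
    _, counts, _, _ = small_dataset
    # multinomial conservation: each column total is exactly the drawn depth,
    # an integer; all entries non-negative integers
    assert (counts >= 0).all().all()
    assert counts.to_numpy().dtype.kind == "i"
    assert (counts.sum(axis=0) > 0).all()


def test_perfect_copula_gives_identical_within_guild_ranks():
    spec = SyntheticSpec(
        n_taxa=10,
        n_samples=15,
        n_guilds=2,
        guild_size=5,
        within_guild_rho=1.0,
        depth_cv=0.0,
        noise_taxa_fraction=0.0,
        n_env_params=0,
        env_linked_guilds=(),
        seed=3,
    )
    _, _, truth = generate_counts(spec)
    latent = truth.latent.to_numpy()
    ranks = rankdata(latent, axis=1)
    for g_start in (0, 5):
        member_ranks = ranks[g_start : g_start + 5]
        assert (member_ranks == member_ranks[0]).all()


def test_no_guilds_means_near_zero_mean_absolute_rho():
    spec = SyntheticSpec(
        n_taxa=60,
        n_samples=40,
        n_guilds=0,
        guild_size=0,
        noise_taxa_fraction=0.0,
        n_env_params=0,
        env_linked_guilds=(),
        seed=5,
    )
    _, _, truth = generate_counts(spec)
    rho = spearman_matrix(truth.latent).to_numpy()
    off = rho[np.triu_indices_from(rho, k=1)]
    # independent rows: |rho| has mean ~ sqrt(2/pi)/sqrt(n-1) ~= 0.13, far
    # below any signal scale
    assert abs(np.mean(off)) < 0.05
    assert np.mean(np.abs(off)) < 0.2


def test_within_guild_empirical_rho_matches_planted_level():
    spec = SyntheticSpec(
        n_samples=36,
        n_taxa=100,
        n_guilds=4,
        guild_size=10,
        within_guild_rho=0.9,
        seed=1,
    )
    _, _, truth = generate_counts(spec)
    rho = spearman_matrix(truth.latent)
    vals = [rho.loc[a, b] for a, b in truth.planted_edges]
    assert 0.6 <= np.mean(vals) <= 0.95


def test_rho_zero_within_guild_indistinguishable_from_background():
    spec = SyntheticSpec(
        n_samples=40,
        n_taxa=80,
        n_guilds=4,
        guild_size=10,
        within_guild_rho=0.0,
        noise_taxa_fraction=0.0,
        n_env_params=0,
        env_linked_guilds=(),
        seed=13,
    )
    _, _, truth = generate_counts(spec)
    rho = spearman_matrix(truth.latent)
    within = np.array([rho.loc[a, b] for a, b in truth.planted_edges])
    guild_taxa = {t for t, g in truth.guild_membership.items() if g is not None}
    others = [
        rho.loc[a, b]
        for a, b in itertools.combinations(rho.index, 2)
        if (a, b) not in truth.planted_edges and a in guild_taxa
    ]
    thresh_within = np.mean(np.abs(within) > 0.6)
    thresh_between = np.mean(np.abs(np.array(others)) > 0.6)
    assert abs(thresh_within - thresh_between) < 0.05


def test_env_params_track_linked_guild_factors(small_dataset):
    _, counts, env, truth = small_dataset
    # a linked parameter should rank-correlate strongly with its guild's
    # members in the latent field
    (param, guild), *_ = sorted(truth.env_links)
    members = [t for t, g in truth.guild_membership.items() if g == guild]
    combined = pd.concat([truth.latent.loc[members], env.loc[[param]]])
    rho = spearman_matrix(combined)
    assert rho.loc[param, members].mean() > 0.5


def test_spec_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        SyntheticSpec(n_taxa=0).validate()
    with pytest.raises(ValueError):
        SyntheticSpec(within_guild_rho=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticSpec(n_taxa=10, n_guilds=3, guild_size=5).validate()
    with pytest.raises(ValueError):
        SyntheticSpec(depth_mean=0).validate()


def test_truth_json_roundtrip(small_dataset):
    from conet import SyntheticTruth

    _, _, _, truth = small_dataset
    back = SyntheticTruth.from_json(truth.to_json())
    assert back.planted_edges == truth.planted_edges
    assert back.guild_membership == truth.guild_membership
    assert back.env_links == truth.env_links


class TestSimilarityMatrix:
    def test_planted_clusters_recoverable_at_97(self):
        sim = generate_similarity_matrix(4, 2, 98, 90, seed=0)
        from conet import build_nscs

        assignment = build_nscs(sim, threshold=97)
        # round-robin assignment: seqs 0,2 vs 1,3
        assert assignment.member_map["seq0000"] == assignment.member_map["seq0002"]
        assert assignment.member_map["seq0001"] == assignment.member_map["seq0003"]
        assert len(assignment.nsc_ids) == 2

    def test_single_sequence(self):
        sim = generate_similarity_matrix(1, 1, 99, 50, seed=0)
        assert sim.shape == (1, 1)
        assert sim.iloc[0, 0] == 100.0

    def test_symmetric_diagonal_100(self):
        sim = generate_similarity_matrix(20, 4, 97.5, 85, seed=3)
        arr = sim.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 100.0)

    def test_component_recovery_matches_transitive_closure_oracle(self):
        sim = generate_similarity_matrix(30, 5, 97.5, 85, seed=7)
        from conet import build_nscs

        assignment = build_nscs(sim, threshold=97)

        # brute-force transitive closure over the >=97 relation
        ids = list(sim.index)
        reach = {i: {i} for i in ids}
        changed = True
        while changed:
            changed = False
            for a in ids:
                for b in ids:
                    if sim.loc[a, b] >= 97 and not reach[b] <= reach[a]:
                        reach[a] |= reach[b]
                        changed = True
        oracle = {i: min(reach[i]) for i in ids}
        assert assignment.member_map == oracle

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_similarity_matrix(3, 5, 98, 90, seed=0)
        with pytest.raises(ValueError):
            generate_similarity_matrix(5, 2, 90, 95, seed=0)
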