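"""Null-model thresholds and consensus network construction."""

import numpy as np
import pandas as pd
import pytest

from conet import (
    SyntheticSpec,
    build_consensus,
    determine_thresholds,
    generate_counts,
    normalize,
    prevalence_filter,
    spearman_matrix,
)


def frame(rows, index=None):
    rows = np.asarray(rows, dtype=float)
    index = index or [f"r{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=index, columns=[f"s{j}" for j in range(rows.shape[1])])


class TestSpearmanMatrix:
    def test_self_correlation_is_one_and_reversal_minus_one(self):
        df = frame([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        rho = spearman_matrix(df)
        assert rho.loc["r0", "r0"] == pytest.approx(1.0)
        assert rho.loc["r0", "r1"] == pytest.approx(-1.0)

    def test_tie_corrected_rank_formula_oracle(self):
        # two 6-sample rows, one with a tie; oracle: average ranks by hand,
        # then the Pearson product-moment formula on the ranks
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]  # ranks 3, 1.5, 4, 1.5, 5, 6
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]  # ranks 2.5, 4, 1, 5.5, 2.5, 5.5
        rx = np.array([3, 1.5, 4, 1.5, 5, 6])
        ry = np.array([2.5, 4, 1, 5.5, 2.5, 5.5])
        cx, cy = rx - rx.mean(), ry - ry.mean()
        expected = (cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum())
        rho = spearman_matrix(frame([x, y]))
        assert rho.loc["r0", "r1"] == pytest.approx(expected)

    def test_constant_row_reported_missing_not_zero(self):
        rho = spearman_matrix(frame([[1, 1, 1, 1], [1, 2, 3, 4]]))
        assert np.isnan(rho.loc["r0", "r1"])
        assert rho.loc["r1", "r1"] == pytest.approx(1.0)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(frame([[1, 2], [3, 4]]))


@pytest.fixture(scope="module")
def independent_norm():
    spec = SyntheticSpec(
        n_samples=36,
        n_taxa=120,
        n_guilds=0,
        guild_size=0,
        noise_taxa_fraction=0.0,
        n_env_params=0,
        env_linked_guilds=(),
        seed=11,
    )
    counts, _, _ = generate_counts(spec)
    return normalize(prevalence_filter(counts))


class TestDetermineThresholds:
    def test_thresholds_bracket_zero_and_scale_with_samples(self, independent_norm):
        thr = determine_thresholds(independent_norm, n_permutations=100, seed=0)
        assert thr.rho_neg < 0 < thr.rho_pos
        # permutation null of rank correlation at n=36: extreme quantiles
        # well inside (0.2, 0.7)
        assert 0.2 < thr.rho_pos < 0.7

    def test_halving_alpha_does_not_lower_positive_threshold(self, independent_norm):
        a = determine_thresholds(independent_norm, n_permutations=100, alpha=0.02, seed=0)
        b = determine_thresholds(independent_norm, n_permutations=100, alpha=0.01, seed=0)
        assert b.rho_pos >= a.rho_pos
        assert b.rho_neg <= a.rho_neg

    def test_seeded_determinism(self, independent_norm):
        a = determine_thresholds(independent_norm, n_permutations=100, seed=5)
        b = determine_thresholds(independent_norm, n_permutations=100, seed=5)
        assert a.rho_pos == b.rho_pos and a.rho_neg == b.rho_neg
        assert a.null_quantiles == b.null_quantiles

    def test_observed_false_edge_fraction_within_twice_alpha(self, independent_norm):
        alpha = 0.01
        thr = determine_thresholds(
            independent_norm, n_permutations=200, alpha=alpha, seed=11
        )
        rho = spearman_matrix(independent_norm).to_numpy()
        tri = rho[np.triu_indices_from(rho, k=1)]
        frac = np.mean((tri >= thr.rho_pos) | (tri <= thr.rho_neg))
        assert frac <= 2 * alpha

    def test_degenerate_all_constant_rejected(self):
        with pytest.raises(ValueError):
            determine_thresholds(frame([[1, 1, 1], [2, 2, 2]]), n_permutations=100)

    def test_json_roundtrip(self, independent_norm):
        from conet import ThresholdResult

        thr = determine_thresholds(independent_norm, n_permutations=100, seed=1)
        back = ThresholdResult.from_json(thr.to_json())
        assert back.rho_pos == thr.rho_pos
        assert back.alpha == thr.alpha


class TestBuildConsensus:
    def test_unattainable_threshold_gives_empty_network(self, independent_norm):
        from conet import ThresholdResult

        thr = ThresholdResult(rho_pos=1.01, rho_neg=-1.01, n_permutations=0, alpha=0.01)
        net = build_consensus(independent_norm, thr, n_jitter=10, seed=0)
        assert net.number_of_nodes() == 0

    def test_duplicate_rows_always_edge_with_full_persistence(self):
        from conet import ThresholdResult

        rng = np.random.default_rng(3)
        base = rng.normal(size=12)
        data = frame([base, base, rng.normal(size=12), rng.normal(size=12)])
        thr = ThresholdResult(rho_pos=0.9, rho_neg=-0.9, n_permutations=0, alpha=0.01)
        net = build_consensus(data, thr, n_jitter=50, seed=1)
        assert net.has_edge("r0", "r1")
        edge = net.edges["r0", "r1"]
        assert edge["rho"] == pytest.approx(1.0, abs=1e-9)
        assert edge["persistence"] == 1.0

    def test_planted_guild_edges_recovered(self):
        spec = SyntheticSpec(
            n_samples=36, n_taxa=80, n_guilds=2, guild_size=10,
            within_guild_rho=0.95, noise_taxa_fraction=0.1,
            n_env_params=0, env_linked_guilds=(), seed=21,
        )
        counts, _, truth = generate_counts(spec)
        norm = normalize(prevalence_filter(counts))
        thr = determine_thresholds(norm, n_permutations=150, alpha=0.01, seed=22)
        net = build_consensus(norm, thr, n_jitter=100, seed=23)
        recovered = {tuple(sorted(e)) for e in net.edges}
        frac = len(truth.planted_edges & recovered) / len(truth.planted_edges)
        assert frac >= 0.9
        # At this small table size the shared depth denominator couples
        # unplanted taxa noticeably, so the false-edge bound is loose; tight
        # calibration is asserted at the 500-taxon scale elsewhere.
        n_pairs = norm.values.shape[0] * (norm.values.shape[0] - 1) / 2
        false_edges = len(recovered - truth.planted_edges)
        assert false_edges <= 0.05 * n_pairs

    def test_edge_set_shrinks_as_persistence_cutoff_rises(self, independent_norm):
        thr = determine_thresholds(independent_norm, n_permutations=100, alpha=0.05, seed=2)
        edges = []
        for cutoff in (0.3, 0.6, 0.9):
            net = build_consensus(
                independent_norm, thr, n_jitter=60, persistence_cutoff=cutoff, seed=7
            )
            edges.append({tuple(sorted(e)) for e in net.edges})
        assert edges[2] <= edges[1] <= edges[0]

    def test_invalid_persistence_cutoff_rejected(self, independent_norm):
        from conet import ThresholdResult

        thr = ThresholdResult(rho_pos=0.5, rho_neg=-0.5, n_permutations=0, alpha=0.01)
        with pytest.raises(ValueError):
            build_consensus(independent_norm, thr, persistence_cutoff=0.0)

    def test_env_rows_participate_and_are_flagged(self):
        from conet import append_env

        spec = SyntheticSpec(
            n_samples=36, n_taxa=60, n_guilds=2, guild_size=8,
            within_guild_rho=0.95, noise_taxa_fraction=0.0,
            n_env_params=2, env_linked_guilds=(0,), seed=31,
        )
        counts, env, truth = generate_counts(spec)
        norm = append_env(normalize(prevalence_filter(counts)), env)
        thr = determine_thresholds(norm, n_permutations=150, alpha=0.01, seed=32)
        net = build_consensus(norm, thr, n_jitter=100, seed=33)
        assert "env0" in net.nodes and net.nodes["env0"]["is_env"]
        linked_members = {
            t for t, g in truth.guild_membership.items() if g == 0
        }
        assert linked_members & set(net.neighbors("env0"))
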