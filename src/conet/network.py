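"""Permutation null models and consensus co-occurrence networks.

Fixed correlation cutoffs are arbitrary: what counts as a "strong" Spearman
rho depends on the number of samples and the tie structure of the data. This
module instead determines dataset-specific significance thresholds from a
permutation null — each row's values are shuffled independently across
samples (destroying every inter-row association while preserving marginals)
and jittered with low-level noise to break the heavy ties of sparse count
data — and then builds a consensus network whose edges must pass those
thresholds *persistently* across noise-jittered replicates of the observed
table, so that edges hanging on a single tie-break configuration are
discarded.

Two distinct randomizations are involved and kept separate on purpose:
shuffling plus jitter yields the null thresholds; jitter alone, applied to
the intact observed table, yields the persistence (stability) of each edge.

Negative correlations (co-exclusions) are handled symmetrically with their
own threshold; they are retained and flagged when they pass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._util import jitter_scales, rank_rows, row_correlation, spearman_from_values
from .preprocessing import NormalizedTable

__all__ = [
    "ThresholdResult",
    "spearman_matrix",
    "determine_thresholds",
    "build_consensus",
]

_HIST_BINS = 4000  # pooled-null histogram resolution: 5e-4 in rho


@dataclass
class ThresholdResult:
    """Dataset-specific Spearman rho significance thresholds.

    ``alpha`` is the tolerated fraction of null edges of *either* sign among
    all tested pairs: ``rho_pos`` is the (1 - alpha/2) quantile of the pooled
    null rho distribution and ``rho_neg`` the symmetric (alpha/2) quantile,
    so the expected number of null edges (co-occurrence plus co-exclusion)
    is at most ``alpha`` times the number of pairs. ``null_quantiles`` keeps
    the per-permutation extreme-rho summaries behind the pooled estimate.
    """

    rho_pos: float
    rho_neg: float
    n_permutations: int
    alpha: float
    null_quantiles: dict[str, list[float]] = field(default_factory=dict)
    seed: int | None = None
    jitter_relative: float = 1e-6

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Thresholds at reporting precision (full precision kept internally)."""
        return round(self.rho_pos, ndigits), round(self.rho_neg, ndigits)

    def to_json(self) -> str:
        payload = {
            "rho_pos": self.rho_pos,
            "rho_neg": self.rho_neg,
            "rho_pos_rounded": self.rounded()[0],
            "rho_neg_rounded": self.rounded()[1],
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "seed": self.seed,
            "jitter_relative": self.jitter_relative,
            "null_quantiles": self.null_quantiles,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdResult":
        p = json.loads(text)
        return cls(
            rho_pos=p["rho_pos"],
            rho_neg=p["rho_neg"],
            n_permutations=p["n_permutations"],
            alpha=p["alpha"],
            null_quantiles=p.get("null_quantiles", {}),
            seed=p.get("seed"),
            jitter_relative=p.get("jitter_relative", 1e-6),
        )


def _as_values(norm: NormalizedTable | pd.DataFrame) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedTable) else norm


def spearman_matrix(norm: NormalizedTable | pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman rho across samples (average ranks for ties).

    Constant rows have undefined correlations and are reported as NaN, never
    coerced to zero.
    """
    values = _as_values(norm)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    rho = spearman_from_values(values.to_numpy(dtype=float))
    return pd.DataFrame(rho, index=values.index, columns=values.index)


def determine_thresholds(
    norm: NormalizedTable | pd.DataFrame,
    n_permutations: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    jitter_relative: float = 1e-6,
) -> ThresholdResult:
    """Estimate significance thresholds from a row-shuffling null model.

    Each permutation shuffles every row independently across samples and adds
    uniform tie-breaking jitter (amplitude ``jitter_relative`` x the row IQR);
    all pairwise rho values are pooled into a fine histogram from which the
    (1 - alpha/2) and (alpha/2) quantiles give the positive and negative
    thresholds, splitting the false-edge budget evenly between the signs.
    """
    values = _as_values(norm).to_numpy(dtype=float)
    n_rows, n_samples = values.shape
    if n_rows < 2 or n_samples < 3:
        raise ValueError("need at least 2 rows and 3 samples")
    if np.all(values.max(axis=1) == values.min(axis=1)):
        raise ValueError("all rows are constant; null model is degenerate")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_permutations < 2:
        raise ValueError("n_permutations must be at least 2")
    if n_permutations < 100:
        warnings.warn(
            "fewer than 100 permutations gives unstable threshold quantiles",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    scales = jitter_scales(values, jitter_relative)
    iu = np.triu_indices(n_rows, k=1)
    edges = np.linspace(-1.0, 1.0, _HIST_BINS + 1)
    hist = np.zeros(_HIST_BINS, dtype=np.int64)
    q_pos = np.empty(n_permutations)
    q_neg = np.empty(n_permutations)
    half = alpha / 2.0

    for p in range(n_permutations):
        shuffled = rng.permuted(values, axis=1)
        shuffled += rng.uniform(-1.0, 1.0, size=shuffled.shape) * scales[:, None]
        rho = row_correlation(rank_rows(shuffled))
        tri = rho[iu]
        hist += np.histogram(tri, bins=edges)[0]
        q_pos[p] = np.quantile(tri, 1.0 - half)
        q_neg[p] = np.quantile(tri, half)

    cdf = np.cumsum(hist) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    rho_pos = float(np.interp(1.0 - half, cdf, centers))
    rho_neg = float(np.interp(half, cdf, centers))

    result = ThresholdResult(
        rho_pos=rho_pos,
        rho_neg=rho_neg,
        n_permutations=n_permutations,
        alpha=alpha,
        null_quantiles={"pos": q_pos.tolist(), "neg": q_neg.tolist()},
        seed=seed,
        jitter_relative=jitter_relative,
    )
    if not result.rho_neg < 0 < result.rho_pos:
        raise RuntimeError(
            "null thresholds do not bracket zero; data too degenerate for a null model"
        )
    return result


def build_consensus(
    norm: NormalizedTable | pd.DataFrame,
    thresholds: ThresholdResult,
    n_jitter: int = 1000,
    persistence_cutoff: float = 0.5,
    seed: int = 0,
    abundances: dict[str, float] | None = None,
) -> nx.Graph:
    """Build the consensus network of persistently significant correlations.

    The observed table is replicated ``n_jitter`` times under tie-breaking
    jitter only (no shuffling); an edge enters the consensus iff its rho
    passes the positive (or negative) threshold in more than
    ``persistence_cutoff`` of the replicates. Edge weight is the mean rho over
    passing replicates; isolated nodes are dropped. Node attributes carry the
    environmental flag and, when supplied, total read abundance.
    """
    if not 0.0 < persistence_cutoff <= 1.0:
        raise ValueError("persistence_cutoff must lie in (0, 1]")
    if n_jitter < 1:
        raise ValueError("n_jitter must be positive")

    table = _as_values(norm)
    is_env = (
        norm.is_env
        if isinstance(norm, NormalizedTable)
        else pd.Series(False, index=table.index)
    )
    values = table.to_numpy(dtype=float)
    n_rows = values.shape[0]
    rng = np.random.default_rng(seed)
    scales = jitter_scales(values, thresholds.jitter_relative)

    pos_hits = np.zeros((n_rows, n_rows), dtype=np.int32)
    neg_hits = np.zeros((n_rows, n_rows), dtype=np.int32)
    pos_rho_sum = np.zeros((n_rows, n_rows))
    neg_rho_sum = np.zeros((n_rows, n_rows))

    for _ in range(n_jitter):
        jittered = values + rng.uniform(-1.0, 1.0, size=values.shape) * scales[:, None]
        rho = row_correlation(rank_rows(jittered))
        with np.errstate(invalid="ignore"):
            pos = rho >= thresholds.rho_pos
            neg = rho <= thresholds.rho_neg
        pos_hits += pos
        neg_hits += neg
        pos_rho_sum += np.where(pos, rho, 0.0)
        neg_rho_sum += np.where(neg, rho, 0.0)

    graph = nx.Graph()
    graph.graph.update(
        rho_pos=thresholds.rho_pos,
        rho_neg=thresholds.rho_neg,
        alpha=thresholds.alpha,
        n_jitter=n_jitter,
        persistence_cutoff=persistence_cutoff,
        seed=seed,
    )
    ids = list(table.index)
    iu = np.triu_indices(n_rows, k=1)
    min_hits = persistence_cutoff * n_jitter
    for i, j in zip(*iu):
        ph, nh = int(pos_hits[i, j]), int(neg_hits[i, j])
        if ph <= min_hits and nh <= min_hits:
            continue
        if ph >= nh:
            sign, hits, mean_rho = 1, ph, pos_rho_sum[i, j] / ph
        else:
            sign, hits, mean_rho = -1, nh, neg_rho_sum[i, j] / nh
        u, v = ids[i], ids[j]
        graph.add_edge(
            u,
            v,
            rho=float(mean_rho),
            sign=sign,
            persistence=hits / n_jitter,
        )
    for node in graph.nodes:
        graph.nodes[node]["is_env"] = bool(is_env.get(node, False))
        if abundances is not None:
            graph.nodes[node]["abundance"] = float(abundances.get(node, 0.0))
    return graph
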