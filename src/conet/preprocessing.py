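"""Prevalence filtering, depth-aware normalization, environmental co-rows.

Read counts from amplicon sequencing are compositional: each sample's counts
are constrained by its sequencing depth, not by absolute abundance. Before
rank-correlation analysis the count table is therefore (a) stripped of taxa
occurring in less than a minimum fraction of samples, and (b) log-ratio
normalized against per-sample depth, centred on the median depth so values
keep an interpretable scale. Because Spearman statistics depend only on
within-row ranks, the exact normalization variant is low-stakes; a rank-only
variant is provided for sensitivity checks.

Environmental parameters (temperature, oxygen, conductivity, ...) are
appended as extra rows so they enter the correlation analysis exactly like
taxa. They are measurements, not compositions, and are deliberately neither
prevalence-filtered nor log-transformed (winter temperatures can be negative,
saturations are percentages).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalizedTable", "prevalence_filter", "normalize", "append_env"]

logger = logging.getLogger(__name__)


@dataclass
class NormalizedTable:
    """Normalized abundance values plus per-row environmental flags."""

    values: pd.DataFrame
    is_env: pd.Series
    variant: str = "log-ratio"

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def taxon_rows(self) -> pd.DataFrame:
        return self.values.loc[~self.is_env]

    def env_rows(self) -> pd.DataFrame:
        return self.values.loc[self.is_env]


def prevalence_filter(counts: pd.DataFrame, min_prevalence: float = 0.10) -> pd.DataFrame:
    """Drop taxa occurring in fewer than ``min_prevalence`` of the samples.

    A taxon is retained when it has nonzero counts in at least
    ``ceil(min_prevalence * n_samples)`` samples, i.e. taxa present in
    strictly less than the threshold fraction are removed (with 38 samples
    and the default 10%, presence in 3 samples is removed, 4 retained).
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must lie in [0, 1]")
    needed = math.ceil(min_prevalence * counts.shape[1])
    present = (counts > 0).sum(axis=1)
    return counts.loc[present >= needed]


def normalize(
    counts: pd.DataFrame,
    variant: str = "log-ratio",
    pseudocount: float = 1.0,
) -> NormalizedTable:
    """Log-ratio normalize a count table against per-sample depth.

    ``log-ratio``:  value(i, j) = log(count + pseudocount) - log(depth_j)
    + log(median depth), where depth_j is sample j's column total. All samples
    at equal depth reduce this to a constant shift of log counts, leaving
    ranks (hence Spearman correlations) untouched; unequal depths are divided
    out. A zero count in a median-depth sample maps to 0.

    ``rank``: each row replaced by the ranks of its depth-corrected
    abundances, a variant that discards everything but order.
    """
    depths = counts.sum(axis=0).astype(float)
    zero = depths[depths <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total reads: {list(zero.index)}")
    if variant == "log-ratio":
        med = float(np.median(depths))
        vals = (
            np.log(counts.to_numpy(dtype=float) + pseudocount)
            - np.log(depths.to_numpy())[None, :]
            + np.log(med)
        )
    elif variant == "rank":
        from scipy.stats import rankdata

        rel = counts.to_numpy(dtype=float) / depths.to_numpy()[None, :]
        vals = rankdata(rel, axis=1, method="average")
    else:
        raise ValueError(f"unknown normalization variant: {variant!r}")
    values = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    is_env = pd.Series(False, index=counts.index)
    return NormalizedTable(values=values, is_env=is_env, variant=variant)


def append_env(norm: NormalizedTable, env: pd.DataFrame) -> NormalizedTable:
    """Append environmental parameter rows, untransformed, flagged is_env.

    Samples are aligned by id (the environmental table's column order is
    irrelevant); parameters with missing values in the retained samples are
    dropped with a logged warning. An empty environmental table is a no-op.
    """
    if env.shape[0] == 0:
        return NormalizedTable(norm.values.copy(), norm.is_env.copy(), norm.variant)
    common = [s for s in norm.sample_ids if s in env.columns]
    if not common:
        raise ValueError("no overlapping samples between tables")
    values = norm.values[common]
    env_aligned = env[common].astype(float)

    incomplete = env_aligned.index[env_aligned.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping environmental parameters with missing values: %s",
            list(incomplete),
        )
        env_aligned = env_aligned.drop(index=incomplete)

    dup = set(values.index) & set(env_aligned.index)
    if dup:
        raise ValueError(f"environmental ids collide with taxon ids: {sorted(dup)[:5]}")

    out_vals = pd.concat([values, env_aligned])
    out_vals.index.name = values.index.name
    is_env = pd.Series(
        [False] * values.shape[0] + [True] * env_aligned.shape[0], index=out_vals.index
    )
    return NormalizedTable(values=out_vals, is_env=is_env, variant=norm.variant)
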