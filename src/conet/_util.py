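"""Shared numerical helpers: seeding, ranking, rank correlation."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.stats import rankdata

MAX_SEED = 2**31


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed deterministically from a master seed.

    Uses SHA-256 of ``"<master>:<stage>"`` so that every randomized stage of
    a pipeline run gets an independent, reproducible stream.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def rank_rows(values: np.ndarray) -> np.ndarray:
    """Rank each row across columns, averaging ties."""
    return rankdata(values, axis=1, method="average")


def row_correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between all row pairs.

    Rows with zero variance yield NaN against every partner (including
    themselves): a constant profile carries no ordering information, so its
    correlations are undefined rather than zero.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 0
    unit = np.zeros_like(centered)
    unit[ok] = centered[ok] / norms[ok, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    idx = np.flatnonzero(ok)
    corr[idx, idx] = 1.0
    return corr


def spearman_from_values(values: np.ndarray) -> np.ndarray:
    """Spearman rho between all row pairs (average ranks for ties)."""
    return row_correlation(rank_rows(values))


def jitter_scales(values: np.ndarray, relative: float = 1e-6) -> np.ndarray:
    """Per-row noise amplitude for tie-breaking jitter.

    Scaled to the interquartile range so the noise is far below signal scale;
    falls back to the full range, then to 1, for degenerate rows.
    """
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    iqr = q75 - q25
    rng_width = values.max(axis=1) - values.min(axis=1)
    base = np.where(iqr > 0, iqr, np.where(rng_width > 0, rng_width, 1.0))
    return relative * base
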