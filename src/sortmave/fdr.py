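"""Bootstrap false-discovery rates for variant scores.

Confidence that a variant's score differs from wild type is estimated
non-parametrically, with no assumption on the distribution of barcode scores
or their errors.  For variant ``v`` with ``k`` barcode scores pooled across
all biological replicates, the pooled score is

    B_v = log2( mean of the k barcode scores / mean of all WT barcode scores )

so that 0 is wild-type-like, matching the sign convention of the per-variant
function score.  The null distribution is built by resampling: 10,000 sets of
``k`` wild-type barcodes drawn uniformly with replacement, each reduced to its
centred score ``B_wt,i`` the same way.  The FDR is then the fraction of null
draws at least as extreme as ``B_v`` on the relevant side, normalised by the
null mass on that side:

    FDR_v = N(B_wt < B_v) / N(B_wt < 0)   if B_v < 0
    FDR_v = N(B_wt > B_v) / N(B_wt > 0)   if B_v > 0

with a pseudocount of 1 replacing a zero numerator, and FDR_v = 1 by
convention when B_v = 0.  Reported values are clipped to <= 1.  Null
distributions are shared between variants with equal ``k`` (one resample set
per distinct ``k``), and everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .scoring import wt_reference_mask
from .library_design import variant_ids

__all__ = [
    "DEFAULT_N_BOOT",
    "NullDistribution",
    "pooled_barcode_scores",
    "variant_pooled_score",
    "bootstrap_wt_null",
    "compute_fdr",
    "add_fdr",
]

DEFAULT_N_BOOT = 10_000


class DegenerateNullError(ValueError):
    """The bootstrap null has no mass on the side of the observed score."""


@dataclass(frozen=True)
class NullDistribution:
    """Centred bootstrap scores of ``n_boot`` resampled WT barcode sets."""

    values: np.ndarray
    k: int
    seed: int

    @property
    def n_boot(self) -> int:
        return len(self.values)


def pooled_barcode_scores(
    barcode_tables: Mapping[int, pd.DataFrame],
    bvmap: pd.DataFrame,
    wt_policy: str = "wt_or_synonymous",
) -> pd.DataFrame:
    """Pool per-replicate barcode scores into one table with variant labels.

    Returns columns ``variant, score, is_wt`` (one row per barcode per
    replicate in which it survived the read filter).
    """
    frames = []
    for rep, table in sorted(barcode_tables.items()):
        joined = table.merge(
            bvmap[["barcode", "position", "wt_aa", "alt_aa"]], on="barcode", how="inner"
        )
        joined["variant"] = variant_ids(joined)
        joined["is_wt"] = wt_reference_mask(joined, wt_policy)
        frames.append(joined[["variant", "score", "is_wt"]])
    return pd.concat(frames, ignore_index=True)


def variant_pooled_score(scores: np.ndarray, wt_mean: float) -> float:
    """Centred pooled score ``B_v`` of one variant's barcode scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 1:
        raise ValueError("variant has no barcode scores")
    return float(np.log2(scores.mean() / wt_mean))


def bootstrap_wt_null(
    wt_scores: np.ndarray,
    k: int,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> NullDistribution:
    """Null of centred scores for resampled size-``k`` WT barcode sets."""
    wt_scores = np.asarray(wt_scores, dtype=float)
    if wt_scores.size < 1:
        raise ValueError("empty wild-type reference pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    idx = rng.integers(0, wt_scores.size, size=(n_boot, k))
    means = wt_scores[idx].mean(axis=1)
    values = np.log2(means / wt_scores.mean())
    return NullDistribution(values=values, k=k, seed=seed)


def compute_fdr(b_v: float, null: NullDistribution) -> float:
    """Sided bootstrap FDR of one pooled variant score against the null."""
    if b_v == 0.0:
        return 1.0
    values = null.values
    if b_v < 0:
        numer = int((values < b_v).sum())
        denom = int((values < 0).sum())
    else:
        numer = int((values > b_v).sum())
        denom = int((values > 0).sum())
    if denom == 0:
        raise DegenerateNullError(
            "bootstrap null has no mass on the observed score's side"
        )
    if numer == 0:
        numer = 1  # pseudocount
    return min(numer / denom, 1.0)


def add_fdr(
    variant_table: pd.DataFrame,
    barcode_tables: Mapping[int, pd.DataFrame],
    bvmap: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    wt_policy: str = "wt_or_synonymous",
) -> pd.DataFrame:
    """Attach ``B_v`` and ``fdr`` columns to an assay's variant score table.

    ``barcode_tables`` are the per-replicate barcode score tables of the same
    assay (the pooled k per variant is the total number of surviving barcode
    observations across replicates).  One null distribution is bootstrapped
    per distinct k.
    """
    pooled = pooled_barcode_scores(barcode_tables, bvmap, wt_policy)
    wt_scores = pooled.loc[pooled["is_wt"], "score"].to_numpy()
    if wt_scores.size == 0:
        raise ValueError("empty wild-type reference pool")
    wt_mean = wt_scores.mean()

    grouped = pooled.groupby("variant")["score"]
    b_v = np.log2(grouped.mean() / wt_mean)
    k_per_variant = grouped.size()

    nulls: dict[int, NullDistribution] = {}
    fdrs = {}
    for variant, b in b_v.items():
        k = int(k_per_variant[variant])
        if k not in nulls:
            nulls[k] = bootstrap_wt_null(wt_scores, k, n_boot, seed)
        fdrs[variant] = compute_fdr(float(b), nulls[k])

    out = variant_table.copy()
    out["B_v"] = out["variant"].map(b_v)
    out["fdr"] = out["variant"].map(fdrs)
    out["n_boot"] = n_boot
    out["fdr_seed"] = seed
    return out
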