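"""Sort-seq scoring: from four-bin barcode counts to variant function scores.

The estimator is the standard weighted-bin-average for sort-seq screens.
For one replicate of one assay:

1. Barcodes with fewer than ``min_reads`` (default 150) reads summed over the
   four bins are removed.
2. Each count is converted to a within-bin frequency,
   ``F[b, bin] = C[b, bin] / sum_b C[b, bin]`` (sequencing depth differs per
   bin, so frequencies rather than counts are comparable across bins).
3. The barcode score is the weighted average of its frequencies with bin
   weights (0.25, 0.5, 0.75, 1):
   ``S_b = sum_bin F[b, bin] * w_bin / sum_bin F[b, bin]`` — bounded by the
   smallest and largest weight.
4. The replicate-level variant score is the ratio of the variant's mean
   barcode score to the wild-type mean barcode score, and the final variant
   score is ``log2`` of the across-replicate mean of those ratios:
   0 = wild-type-like, negative = loss of function.

Wild-type reference barcodes are, by default, those whose clone carries an
unmutated or synonymous-only coding sequence.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import SYNONYMOUS, variant_ids

__all__ = [
    "BIN_COLUMNS",
    "DEFAULT_BIN_WEIGHTS",
    "DegenerateBinError",
    "filter_low_read_barcodes",
    "compute_bin_frequencies",
    "compute_barcode_scores",
    "compute_variant_scores",
    "aggregate_replicates",
    "score_replicate",
    "score_assay",
]

BIN_COLUMNS = ["bin1", "bin2", "bin3", "bin4"]
FREQ_COLUMNS = ["f_bin1", "f_bin2", "f_bin3", "f_bin4"]
DEFAULT_BIN_WEIGHTS = (0.25, 0.5, 0.75, 1.0)


class DegenerateBinError(ValueError):
    """A bin has zero total reads among retained barcodes."""


def _check_counts(table: pd.DataFrame) -> None:
    missing = [c for c in BIN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing bin columns {missing}")
    if (table[BIN_COLUMNS].to_numpy() < 0).any():
        raise ValueError("negative counts in bin count table")


def filter_low_read_barcodes(table: pd.DataFrame, min_reads: int = 150) -> pd.DataFrame:
    """Retain barcodes with at least ``min_reads`` reads across the 4 bins."""
    _check_counts(table)
    total = table[BIN_COLUMNS].sum(axis=1)
    return table.loc[total >= min_reads].copy()


def compute_bin_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Within-bin barcode frequencies ``F[b, bin]``; each bin column sums to 1.

    Raises :class:`DegenerateBinError` if any bin has zero total reads among
    the retained barcodes.
    """
    _check_counts(table)
    counts = table[BIN_COLUMNS].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = [BIN_COLUMNS[i] for i in np.flatnonzero(totals == 0)]
        raise DegenerateBinError(f"no reads in bin(s) {empty} after filtering")
    out = table[["barcode"]].copy()
    out[FREQ_COLUMNS] = counts / totals
    return out


def compute_barcode_scores(
    freqs: pd.DataFrame, weights: Sequence[float] = DEFAULT_BIN_WEIGHTS
) -> pd.DataFrame:
    """Frequency-weighted barcode scores ``S_b`` (one row per barcode)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("exactly four bin weights required")
    f = freqs[FREQ_COLUMNS].to_numpy(dtype=float)
    denom = f.sum(axis=1)
    if (denom == 0).any():
        raise ValueError("barcode with all-zero frequencies")
    out = freqs[["barcode"]].copy()
    out["score"] = (f * w).sum(axis=1) / denom
    return out


def wt_reference_mask(bvmap: pd.DataFrame, wt_policy: str = "wt_or_synonymous") -> pd.Series:
    """Boolean mask over map rows marking wild-type reference barcodes."""
    if wt_policy == "wt_or_synonymous":
        return bvmap["alt_aa"].eq(SYNONYMOUS) | bvmap["alt_aa"].eq(bvmap["wt_aa"])
    if wt_policy == "wt_only":
        return bvmap["wt_aa"].eq(SYNONYMOUS)
    raise ValueError(f"unknown wt_policy {wt_policy!r}")


def compute_variant_scores(
    barcode_scores: pd.DataFrame,
    bvmap: pd.DataFrame,
    wt_policy: str = "wt_or_synonymous",
) -> pd.DataFrame:
    """Replicate-level variant score ratios ``S_v = mean(S_b) / mean(S_b, WT)``.

    Variants with no retained barcode in this replicate are simply absent
    from the output (missing, not zero).  Returns columns
    ``variant, ratio, n_barcodes``.
    """
    joined = barcode_scores.merge(
        bvmap[["barcode", "position", "wt_aa", "alt_aa"]], on="barcode", how="inner"
    )
    wt_mask = wt_reference_mask(joined, wt_policy)
    if not wt_mask.any():
        raise ValueError("wild-type reference set is empty after filtering")
    wt_mean = joined.loc[wt_mask, "score"].mean()
    joined["variant"] = variant_ids(joined)
    grouped = joined.groupby("variant")["score"].agg(["mean", "size"])
    out = pd.DataFrame(
        {
            "variant": grouped.index,
            "ratio": grouped["mean"].to_numpy() / wt_mean,
            "n_barcodes": grouped["size"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def aggregate_replicates(
    ratio_tables: Mapping[int, pd.DataFrame], min_replicates: int = 1
) -> pd.DataFrame:
    """Across-replicate variant score: ``log2(mean of replicate ratios)``.

    The mean runs over the replicates in which the variant was scored;
    variants present in fewer than ``min_replicates`` replicates are dropped.
    Returns columns ``variant, score, n_replicates, n_barcodes`` plus one
    ``ratio_rep<r>`` column per replicate.
    """
    if not ratio_tables:
        raise ValueError("no replicate tables supplied")
    wide = None
    barcode_counts = None
    for rep, table in sorted(ratio_tables.items()):
        cols = table.set_index("variant")[["ratio", "n_barcodes"]]
        r = cols[["ratio"]].rename(columns={"ratio": f"ratio_rep{rep}"})
        wide = r if wide is None else wide.join(r, how="outer")
        k = cols["n_barcodes"]
        barcode_counts = k if barcode_counts is None else barcode_counts.add(k, fill_value=0)
    ratio_cols = [c for c in wide.columns if c.startswith("ratio_rep")]
    n_reps = wide[ratio_cols].notna().sum(axis=1)
    keep = n_reps >= min_replicates
    wide = wide.loc[keep]
    out = wide.copy()
    out["score"] = np.log2(wide[ratio_cols].mean(axis=1, skipna=True))
    out["n_replicates"] = n_reps.loc[keep].astype(int)
    out["n_barcodes"] = barcode_counts.loc[keep].astype(int)
    return out.reset_index().rename(columns={"index": "variant"})


def score_replicate(
    counts: pd.DataFrame,
    bvmap: pd.DataFrame,
    min_reads: int = 150,
    weights: Sequence[float] = DEFAULT_BIN_WEIGHTS,
    wt_policy: str = "wt_or_synonymous",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full single-replicate pass: filter, frequencies, S_b, ratios.

    Returns ``(barcode_scores, variant_ratios)``.
    """
    retained = filter_low_read_barcodes(counts, min_reads)
    freqs = compute_bin_frequencies(retained)
    barcode_scores = compute_barcode_scores(freqs, weights)
    ratios = compute_variant_scores(barcode_scores, bvmap, wt_policy)
    return barcode_scores, ratios


def score_assay(
    replicate_counts: Mapping[int, pd.DataFrame],
    bvmap: pd.DataFrame,
    min_reads: int = 150,
    weights: Sequence[float] = DEFAULT_BIN_WEIGHTS,
    wt_policy: str = "wt_or_synonymous",
    min_replicates: int = 1,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Score one assay across replicates.

    Returns ``(variant_table, per_replicate_barcode_scores)`` where the
    variant table carries per-replicate ratio columns, the aggregated log2
    ``score`` and variant annotations (position, wt_aa, alt_aa).
    """
    barcode_tables: dict[int, pd.DataFrame] = {}
    ratio_tables: dict[int, pd.DataFrame] = {}
    for rep, counts in replicate_counts.items():
        bscores, ratios = score_replicate(counts, bvmap, min_reads, weights, wt_policy)
        barcode_tables[rep] = bscores
        ratio_tables[rep] = ratios
    table = aggregate_replicates(ratio_tables, min_replicates)
    anno = bvmap.assign(variant=variant_ids(bvmap))[
        ["variant", "position", "wt_aa", "alt_aa"]
    ].drop_duplicates("variant")
    table = table.merge(anno, on="variant", how="left")
    return table, barcode_tables
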